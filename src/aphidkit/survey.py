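"""Biotype survey tables: proportions by collection time, host and morph.

Field surveys report, per (collection time, host plant, morph) group,
the total number of aphids sequenced and the percentage classified as
cotton biotype, cucumber biotype, or other aphid species.  Ambiguous
calls (an ambiguity code at a diagnostic site) have no counterpart in
such tables; they are excluded from the percentage denominator and
reported in a separate column.  Raw fractions are kept as exact
rationals alongside the integer-rounded display percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .biotyping import AMBIGUOUS, COTTON, CUCUMBER, OTHER_SPECIES, BiotypeCall
from .lifetable import round_half_up

logger = logging.getLogger(__name__)

__all__ = ["SurveyRow", "SurveyTable", "summarize_survey", "render_table"]

DEFAULT_GROUP_BY = ("collection_time", "host", "morph")


@dataclass(frozen=True)
class SurveyRow:
    """Counts and exact fractions for one survey group."""

    key: tuple[str, ...]
    total: int  # unambiguous calls (the percentage denominator)
    n_cotton: int
    n_cucumber: int
    n_other: int
    n_ambiguous: int

    @property
    def frac_cotton(self) -> Fraction:
        return Fraction(self.n_cotton, self.total) if self.total else Fraction(0)

    @property
    def frac_cucumber(self) -> Fraction:
        return Fraction(self.n_cucumber, self.total) if self.total else Fraction(0)

    @property
    def frac_other(self) -> Fraction:
        return Fraction(self.n_other, self.total) if self.total else Fraction(0)

    @property
    def pct_cotton(self) -> float:
        return round_half_up(float(100 * self.frac_cotton))

    @property
    def pct_cucumber(self) -> float:
        return round_half_up(float(100 * self.frac_cucumber))

    @property
    def pct_other(self) -> float:
        return round_half_up(float(100 * self.frac_other))


@dataclass(frozen=True)
class SurveyTable:
    group_by: tuple[str, ...]
    rows: tuple[SurveyRow, ...]


def _group_key(
    call: BiotypeCall,
    meta: Mapping[str, str],
    group_by: Sequence[str],
) -> tuple[str, ...]:
    key = []
    for field in group_by:
        if field not in meta or meta[field] in (None, ""):
            raise ValueError(
                f"record {call.id!r} is missing grouping metadata {field!r}"
            )
        key.append(str(meta[field]))
    return tuple(key)


def summarize_survey(
    calls: Iterable[BiotypeCall],
    metadata: Mapping[str, Mapping[str, str]],
    group_by: Sequence[str] = DEFAULT_GROUP_BY,
) -> SurveyTable:
    """Aggregate biotype calls into a proportion table.

    ``metadata`` maps record id to its grouping fields.  Rows are sorted
    by group key, so the table is invariant under input permutation.
    Groups with only ambiguous calls get total = 0 with a warning.
    """
    group_by = tuple(group_by)
    counts: dict[tuple[str, ...], dict[str, int]] = {}
    for call in calls:
        if call.id not in metadata:
            raise ValueError(f"record {call.id!r} has no metadata entry")
        key = _group_key(call, metadata[call.id], group_by)
        bucket = counts.setdefault(
            key, {COTTON: 0, CUCUMBER: 0, OTHER_SPECIES: 0, AMBIGUOUS: 0}
        )
        bucket[call.call] += 1
    rows = []
    for key in sorted(counts):
        c = counts[key]
        total = c[COTTON] + c[CUCUMBER] + c[OTHER_SPECIES]
        if total == 0:
            logger.warning("survey group %s has no unambiguous calls", key)
        rows.append(
            SurveyRow(
                key=key,
                total=total,
                n_cotton=c[COTTON],
                n_cucumber=c[CUCUMBER],
                n_other=c[OTHER_SPECIES],
                n_ambiguous=c[AMBIGUOUS],
            )
        )
    return SurveyTable(group_by=group_by, rows=tuple(rows))


def render_table(table: SurveyTable) -> str:
    """Deterministic TSV rendering with integer half-up percentages.

    Column order follows the printed survey layout (grouping keys,
    total, cotton %, cucumber %, other %), then the ambiguous count and
    the raw fractions as auxiliary columns.  Idempotent: re-rendering
    the same table is byte-identical.
    """
    header = list(table.group_by) + [
        "total",
        "pct_cotton",
        "pct_cucumber",
        "pct_other",
        "n_ambiguous",
        "frac_cotton",
        "frac_cucumber",
        "frac_other",
    ]
    lines = ["\t".join(header)]
    for row in table.rows:
        lines.append(
            "\t".join(
                list(row.key)
                + [
                    str(row.total),
                    str(int(row.pct_cotton)),
                    str(int(row.pct_cucumber)),
                    str(int(row.pct_other)),
                    str(row.n_ambiguous),
                    str(row.frac_cotton),
                    str(row.frac_cucumber),
                    str(row.frac_other),
                ]
            )
        )
    return "\n".join(lines) + "\n"
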
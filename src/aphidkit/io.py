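"""Validated file I/O for the pipeline's tabular formats.

All tables are plain text: cohort records come in as CSV (one row per
replicate-day), everything the pipeline writes is TSV with fixed column
orders so reruns diff cleanly.  Schema violations are reported with the
offending row or record so field data can be fixed at the source.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .biotyping import BiotypeCall
from .lifetable import Cohort, CohortValidationError, TreatmentSummary

logger = logging.getLogger(__name__)

__all__ = [
    "read_cohorts_csv",
    "write_summary_tsv",
    "write_replicate_tsv",
    "read_replicate_tsv",
    "read_metadata_csv",
    "write_calls_tsv",
    "read_calls_tsv",
]

COHORT_COLUMNS = ["replicate_id", "day", "n_alive", "n_offspring"]
SUMMARY_COLUMNS = [
    "treatment", "n_reps", "R0_mean", "R0_sd", "T_mean", "T_sd",
    "rm_mean", "rm_sd", "n_undefined",
]
REPLICATE_COLUMNS = ["treatment", "replicate_id", "R0", "T", "rm", "defined"]
CALL_COLUMNS = ["id", "call", "genotype", "orientation", "reason"]


def read_cohorts_csv(
    path: str | Path, treatment_col: str | None = None
) -> dict[str, list[Cohort]]:
    """Read daily cohort records grouped by treatment.

    Required columns: ``replicate_id, day, n_alive, n_offspring``.
    Optional: ``initial_n`` (otherwise inferred as the first day's
    ``n_alive``) and a treatment column; without one, every replicate
    lands in the ``"all"`` treatment.  Validation failures name the row.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no cohort rows found")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if treatment_col is not None and treatment_col not in df.columns:
        raise ValueError(f"{path}: treatment column {treatment_col!r} not found")
    for col in ["day", "n_alive", "n_offspring"]:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col!r} at row {bad.index[0] + 2}"  # header is row 1
            )
    out: dict[str, list[Cohort]] = {}
    group_cols = [treatment_col, "replicate_id"] if treatment_col else ["replicate_id"]
    for key, grp in df.groupby(group_cols, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        treatment = str(key[0]) if treatment_col else "all"
        rep_id = str(key[-1])
        grp = grp.sort_values("day")
        if "initial_n" in grp.columns:
            initial_n = int(grp["initial_n"].iloc[0])
        else:
            initial_n = int(grp["n_alive"].iloc[0])
        try:
            cohort = Cohort.from_rows(
                rep_id,
                initial_n,
                zip(grp["day"], grp["n_alive"], grp["n_offspring"]),
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"{path}: {exc}") from exc
        out.setdefault(treatment, []).append(cohort)
    return out


def _fmt(value: float | None, ndigits: int = 6) -> str:
    if value is None:
        return "NA"
    return f"{value:.{ndigits}g}"


def write_summary_tsv(summaries: Sequence[TreatmentSummary], path: str | Path) -> None:
    """Treatment-level table: mean and SD per parameter plus exclusions."""
    lines = ["\t".join(SUMMARY_COLUMNS)]
    for s in summaries:
        lines.append(
            "\t".join(
                [
                    s.label,
                    str(s.n_replicates),
                    _fmt(s.r0_mean),
                    _fmt(s.r0_sd),
                    _fmt(s.t_mean),
                    _fmt(s.t_sd),
                    _fmt(s.rm_mean),
                    _fmt(s.rm_sd),
                    str(s.n_undefined),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_replicate_tsv(
    summaries: Sequence[TreatmentSummary],
    cohort_ids: Mapping[str, Sequence[str]],
    path: str | Path,
) -> None:
    """Replicate-level parameter table (input for group comparisons)."""
    lines = ["\t".join(REPLICATE_COLUMNS)]
    for s in summaries:
        ids = cohort_ids[s.label]
        for rep_id, p in zip(ids, s.params):
            lines.append(
                "\t".join(
                    [
                        s.label,
                        rep_id,
                        _fmt(p.r0),
                        _fmt(p.t),
                        _fmt(p.rm),
                        str(p.defined).lower(),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_replicate_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in REPLICATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_metadata_csv(path: str | Path) -> dict[str, dict[str, str]]:
    """Sidecar metadata ``id,host,collection_time,morph`` keyed by id."""
    df = pd.read_csv(path, dtype=str)
    if "id" not in df.columns:
        raise ValueError(f"{path}: metadata must have an 'id' column")
    dupes = df["id"][df["id"].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate metadata id {dupes.iloc[0]!r}")
    return {
        str(row["id"]): {k: row[k] for k in df.columns if k != "id" and pd.notna(row[k])}
        for _, row in df.iterrows()
    }


def write_calls_tsv(calls: Sequence[BiotypeCall], path: str | Path) -> None:
    lines = ["\t".join(CALL_COLUMNS)]
    for c in calls:
        lines.append(
            "\t".join(
                [c.id, c.call, c.genotype or "NA", c.orientation or "NA", c.reason]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_calls_tsv(path: str | Path) -> list[BiotypeCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    calls = []
    for _, row in df.iterrows():
        calls.append(
            BiotypeCall(
                id=str(row["id"]),
                call=str(row["call"]),
                genotype=None if row["genotype"] == "NA" else str(row["genotype"]),
                orientation=None if row["orientation"] == "NA" else str(row["orientation"]),
                reason=str(row["reason"]),
            )
        )
    return calls
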
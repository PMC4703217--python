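"""Nonparametric comparison of demographic parameters between treatments.

Host-transfer tables compare small samples of per-replicate parameters
(R0, T, r_m) or daily survival percentages, using the Mann-Whitney U
test for two groups and the Kruskal-Wallis test for three or more.
Significance is displayed either as star marks (``*`` for P < 0.05,
``**`` for P < 0.01) or as a compact letter display in which two groups
share no letter exactly when their pairwise comparison is significant.

Two-sample p-values are exact (full enumeration of rank assignments)
for small tie-free samples and use the normal approximation with tie
and continuity corrections otherwise; Kruskal-Wallis uses the usual
chi-square approximation with k - 1 degrees of freedom.  All tests are
two-sided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonResult",
    "GroupLetters",
    "LetterAssignment",
    "EXACT_THRESHOLD",
    "mann_whitney_u",
    "kruskal_wallis",
    "significance_marks",
    "pairwise_letters",
]

# combined sample size at or below which the exact two-sample p is used
EXACT_THRESHOLD = 10


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "approximate"
    groups: tuple[str, ...]


@dataclass(frozen=True)
class GroupLetters:
    label: str
    mean: float
    letters: str


@dataclass(frozen=True)
class LetterAssignment:
    """Compact letter display over a set of groups at a fixed alpha."""

    alpha: float
    entries: tuple[GroupLetters, ...]

    def letters(self) -> dict[str, str]:
        return {e.label: e.letters for e in self.entries}


def _as_sample(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(list(x), dtype=float)
    if arr.size == 0:
        raise ValueError(f"sample {name!r} is empty")
    return arr


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    The exact null distribution (enumeration over rank assignments) is
    used when the combined sample size is at most ``EXACT_THRESHOLD``
    and there are no ties; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    xa = _as_sample(a, labels[0])
    xb = _as_sample(b, labels[1])
    combined = np.concatenate([xa, xb])
    tie_free = np.unique(combined).size == combined.size
    if tie_free and combined.size <= EXACT_THRESHOLD:
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            xa, xb, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "approximate"
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method=method,
        groups=tuple(labels),
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> ComparisonResult:
    """Kruskal-Wallis H test (tie-corrected) across two or more groups."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    samples = [_as_sample(g, str(lab)) for g, lab in zip(groups, labels)]
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        # every observation identical: no rank variation, H = 0 by definition
        return ComparisonResult(0.0, 1.0, "approximate", tuple(map(str, labels)))
    res = stats.kruskal(*samples)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="approximate",
        groups=tuple(map(str, labels)),
    )


def significance_marks(p_value: float) -> str:
    """Star marks of printed tables: '**' if p < 0.01, '*' if p < 0.05."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value out of [0, 1]: {p_value}")
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def _absorb(letter_sets: list[set[int]]) -> list[set[int]]:
    """Drop empty sets, duplicates, and sets contained in another."""
    kept: list[set[int]] = []
    for s in letter_sets:
        if s and s not in kept and not any(s < other for other in letter_sets):
            kept.append(s)
    return kept


def pairwise_letters(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> LetterAssignment:
    """Compact letter display from all pairwise Mann-Whitney tests.

    Groups are ordered by descending mean; letters are assigned by the
    insert-and-absorb method so that two groups share no letter iff
    their pairwise test is significant at ``alpha`` (optionally
    Bonferroni-adjusted over the number of pairs).  Deterministic given
    the samples and alpha.
    """
    if len(samples) < 2:
        raise ValueError("pairwise_letters requires at least 2 groups")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    labels = sorted(samples, key=lambda k: (-float(np.mean(samples[k])), str(k)))
    n = len(labels)
    n_pairs = n * (n - 1) // 2
    threshold = alpha / n_pairs if bonferroni else alpha
    significant = []
    for i, j in itertools.combinations(range(n), 2):
        res = mann_whitney_u(
            samples[labels[i]], samples[labels[j]], labels=(labels[i], labels[j])
        )
        if res.p_value < threshold:
            significant.append((i, j))

    letter_sets: list[set[int]] = [set(range(n))]
    for i, j in significant:
        split: list[set[int]] = []
        for s in letter_sets:
            if i in s and j in s:
                split.append(s - {i})
                split.append(s - {j})
            else:
                split.append(s)
        letter_sets = _absorb(split)

    # stable letter order: by smallest member index (i.e. highest mean)
    letter_sets.sort(key=lambda s: min(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    entries = []
    for idx, lab in enumerate(labels):
        letters = "".join(
            alphabet[k] for k, s in enumerate(letter_sets) if idx in s
        )
        entries.append(GroupLetters(label=lab, mean=float(np.mean(samples[lab])), letters=letters))
    return LetterAssignment(alpha=threshold, entries=tuple(entries))
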
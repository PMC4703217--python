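"""Synthetic cohorts and marker fragments with known ground truth.

Two generators stand in for the field work of a host-transfer study so
every downstream stage can be tested against an analytic answer.

Cohorts: each of ``n_individuals`` first-stadium nymphs survives day
``x`` independently with probability ``survival_probs[x-1]``; each
survivor then produces a Poisson number of offspring with mean
``fecundity_means[x-1]``.  Under this model the expected net
reproductive rate has the closed form ``E[R0] = sum_x (prod_{i<=x} p_i)
* f_x``, and the expected schedule gives T and r_m through the ordinary
life-table formulas — the simulation's analytic truth.

Marker fragments: cotton- and cucumber-labelled amplicons carry the
respective diagnostic pattern at the marker's offsets inside a
primer-flanked fragment; per-site substitution noise is applied outside
the diagnostic sites.  "Other species" records are random sequences
without the primer.  Every second record is emitted reverse-complemented
so strand handling is always exercised.  The default cohort settings
mirror the host-transfer protocol: cohorts of 10 nymphs, 15 replicates,
and a survival/fecundity schedule whose analytic R0 (~31) and T (~10 d)
are in the range reported for aphids reared on their natal host.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .biotyping import (
    COTTON,
    CUCUMBER,
    OTHER_SPECIES,
    MarkerDefinition,
    SequenceRecord,
    reverse_complement,
)
from .lifetable import (
    Cohort,
    DemographicParams,
    LifeTableSchedule,
    Observation,
    ScheduleRow,
    demographic_parameters,
)

__all__ = [
    "CohortSimConfig",
    "SequenceSimConfig",
    "simulate_cohort",
    "analytic_truth",
    "simulate_marker_sequences",
    "write_fasta",
]

# default daily schedule: juvenile period of 5 days with high survival,
# then 9 reproductive days at ~4.5 nymphs/day -- E[R0] ~ 31, E[T] ~ 10 d
_DEFAULT_SURVIVAL = (0.98,) * 20
_DEFAULT_FECUNDITY = (0.0,) * 5 + (4.5,) * 9 + (0.0,) * 6


@dataclass(frozen=True)
class CohortSimConfig:
    """Bernoulli-survival / Poisson-fecundity cohort simulation settings."""

    n_individuals: int = 10
    survival_probs: tuple[float, ...] = _DEFAULT_SURVIVAL
    fecundity_means: tuple[float, ...] = _DEFAULT_FECUNDITY
    n_replicates: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "survival_probs", tuple(float(p) for p in self.survival_probs))
        object.__setattr__(self, "fecundity_means", tuple(float(f) for f in self.fecundity_means))
        if self.n_individuals <= 0 or self.n_replicates <= 0:
            raise ValueError("n_individuals and n_replicates must be positive")
        if len(self.survival_probs) != len(self.fecundity_means):
            raise ValueError("survival_probs and fecundity_means must have equal length")
        if not self.survival_probs:
            raise ValueError("schedules must cover at least one day")
        if any(not 0.0 <= p <= 1.0 for p in self.survival_probs):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if any(f < 0.0 for f in self.fecundity_means):
            raise ValueError("fecundity means must be >= 0")


@dataclass(frozen=True)
class SequenceSimConfig:
    """Composition and noise settings for a synthetic amplicon batch."""

    n_cotton: int = 20
    n_cucumber: int = 20
    n_other: int = 10
    background_noise: float = 0.0
    fragment_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cotton, self.n_cucumber, self.n_other) < 0:
            raise ValueError("record counts must be >= 0")
        if not 0.0 <= self.background_noise < 1.0:
            raise ValueError("background_noise must lie in [0, 1)")


def simulate_cohort(config: CohortSimConfig) -> list[Cohort]:
    """Simulate ``n_replicates`` cohorts of daily (alive, offspring) records.

    Survival is applied first each day, then the survivors reproduce, so
    a replicate's R0 estimate is unbiased for the analytic value.
    Reproducible: the same config (including seed) gives identical
    cohorts.
    """
    rng = np.random.default_rng(config.seed)
    cohorts = []
    n_days = len(config.survival_probs)
    for rep in range(config.n_replicates):
        alive = config.n_individuals
        obs = []
        for day in range(1, n_days + 1):
            alive = int(rng.binomial(alive, config.survival_probs[day - 1]))
            offspring = (
                int(rng.poisson(alive * config.fecundity_means[day - 1])) if alive else 0
            )
            obs.append(Observation(day=day, n_alive=alive, n_offspring=offspring))
        cohorts.append(
            Cohort(
                replicate_id=f"sim{rep + 1:03d}",
                initial_n=config.n_individuals,
                observations=tuple(obs),
            )
        )
    return cohorts


def expected_schedule(config: CohortSimConfig) -> LifeTableSchedule:
    """The deterministic (x, l_x, m_x) schedule implied by the config."""
    l = np.cumprod(config.survival_probs)
    rows = tuple(
        ScheduleRow(day, float(l[day - 1]), config.fecundity_means[day - 1])
        for day in range(1, len(l) + 1)
    )
    return LifeTableSchedule(rows)


def analytic_truth(config: CohortSimConfig) -> DemographicParams:
    """Closed-form E[R0] = sum_x (prod_{i<=x} p_i) f_x, with T and r_m
    from the expected schedule; undefined when fecundity is all zero."""
    return demographic_parameters(expected_schedule(config))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate(
    rng: np.random.Generator,
    seq: list[str],
    rate: float,
    protected: frozenset[int],
) -> list[str]:
    """Substitute each unprotected site with prob ``rate`` (to a new base)."""
    if rate <= 0.0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if int(i) in protected:
            continue
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(3))]
    return out


def simulate_marker_sequences(
    config: SequenceSimConfig, marker: MarkerDefinition
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Generate labelled synthetic amplicons for a marker definition.

    Biotype records share one randomly drawn core per batch, carry their
    pattern at the diagnostic offsets, and are flanked by the forward
    primer and the reverse complement of the reverse primer.  Noise
    never touches the diagnostic sites or the primers, so the truth
    labels stay exact.  Records at odd indices are reverse-complemented.
    Returns ``(records, truth)`` with truth entries ``(id, label)``.
    """
    if config.fragment_length <= marker.diagnostic_offsets[-1]:
        raise ValueError(
            "fragment_length must exceed the largest diagnostic offset "
            f"({marker.diagnostic_offsets[-1]})"
        )
    rng = np.random.default_rng(config.seed)
    core = list(_random_sequence(rng, config.fragment_length))
    protected = frozenset(marker.diagnostic_offsets)
    tail = reverse_complement(marker.reverse_primer)

    def build(pattern: str) -> str:
        c = list(core)
        for off, base in zip(marker.diagnostic_offsets, pattern):
            c[off] = base
        c = _mutate(rng, c, config.background_noise, protected)
        return marker.forward_primer + "".join(c) + tail

    total_len = len(marker.forward_primer) + config.fragment_length + len(tail)
    plan = (
        [(COTTON, marker.cotton_pattern)] * config.n_cotton
        + [(CUCUMBER, marker.cucumber_pattern)] * config.n_cucumber
        + [(OTHER_SPECIES, None)] * config.n_other
    )
    records: list[SequenceRecord] = []
    truth: list[tuple[str, str]] = []
    for idx, (label, pattern) in enumerate(plan):
        if pattern is not None:
            seq = build(pattern)
        else:
            # fully random sequence: with a 26-nt primer the chance of a
            # spurious <=2-mismatch hit is negligible, but verify anyway
            while True:
                seq = _random_sequence(rng, total_len)
                if not _contains_primer(seq, marker):
                    break
        if idx % 2 == 1:
            seq = reverse_complement(seq)
        rec_id = f"{label}_{idx + 1:04d}"
        records.append(SequenceRecord(id=rec_id, sequence=seq))
        truth.append((rec_id, label))
    return records, truth


def _contains_primer(seq: str, marker: MarkerDefinition) -> bool:
    from .biotyping import _best_primer_match

    for s in (seq, reverse_complement(seq)):
        if _best_primer_match(s, marker.forward_primer, marker.max_primer_mismatches):
            return True
    return False


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as uncompressed FASTA (deterministic byte output)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
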
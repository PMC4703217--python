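"""Cohort life tables for insect host-transfer experiments.

A cohort is started from a fixed number of first-stadium nymphs and
checked daily; the observations are (day, number alive, offspring
produced that day).  From these the classical age-specific schedules are
built:

* ``l_x`` — proportion of the original cohort alive at age ``x`` (days),
* ``m_x`` — offspring per surviving individual on day ``x``,

and the three demographic parameters reported in host-transfer studies:

* net reproductive rate        ``R0 = sum(l_x * m_x)``,
* mean generation time         ``T  = sum(x * l_x * m_x) / R0``,
* intrinsic rate of increase   ``r_m = ln(R0) / T``.

Ages are counted with ``x = 1`` at the first daily check after cohort
initiation (the founding adults are removed after 24 h).  Aphids are
parthenogenetic, so every individual is a reproducing female and ``m_x``
needs no sex-ratio adjustment.  When a treatment produces no offspring
at all, ``R0 = 0`` and ``T`` and ``r_m`` are undefined (``ln 0``); such
replicates are flagged rather than given a numeric value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Observation",
    "Cohort",
    "ScheduleRow",
    "LifeTableSchedule",
    "DemographicParams",
    "TreatmentSummary",
    "SurvivalSummary",
    "CohortValidationError",
    "UndefinedParameterError",
    "build_life_table",
    "net_reproductive_rate",
    "generation_time",
    "intrinsic_rate_of_increase",
    "demographic_parameters",
    "replicate_parameters",
    "pooled_parameters",
    "survival_percent",
    "round_half_up",
]


class CohortValidationError(ValueError):
    """Raised when daily cohort records violate a structural invariant."""


class UndefinedParameterError(ValueError):
    """Raised when T or r_m is requested for a schedule with R0 = 0."""


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables).

    Python's builtin ``round`` is banker's rounding; survey percentages
    and displayed parameters use half-up instead (76.47 -> 76.5 -> 76).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Observation:
    """One daily check: age in days, survivors, offspring produced."""

    day: int
    n_alive: int
    n_offspring: int


@dataclass(frozen=True)
class Cohort:
    """Daily observations for one replicate of a host-transfer treatment.

    Invariants (checked on construction): days strictly increasing and
    >= 1; ``n_alive`` never exceeds ``initial_n`` and never increases;
    no offspring on days with zero survivors.
    """

    replicate_id: str
    initial_n: int
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        if self.initial_n <= 0:
            raise CohortValidationError(
                f"replicate {self.replicate_id!r}: initial_n must be positive, "
                f"got {self.initial_n}"
            )
        if not self.observations:
            raise CohortValidationError(
                f"replicate {self.replicate_id!r}: empty observation list"
            )
        prev_day = 0
        prev_alive = self.initial_n
        for obs in self.observations:
            if obs.day <= prev_day:
                raise CohortValidationError(
                    f"replicate {self.replicate_id!r}: days must be strictly "
                    f"increasing and >= 1 (day {obs.day} after day {prev_day})"
                )
            if obs.n_alive < 0 or obs.n_offspring < 0:
                raise CohortValidationError(
                    f"replicate {self.replicate_id!r}: negative count on day {obs.day}"
                )
            if obs.n_alive > self.initial_n:
                raise CohortValidationError(
                    f"replicate {self.replicate_id!r}: n_alive {obs.n_alive} exceeds "
                    f"initial_n {self.initial_n} on day {obs.day}"
                )
            if obs.n_alive > prev_alive:
                raise CohortValidationError(
                    f"replicate {self.replicate_id!r}: n_alive increases from "
                    f"{prev_alive} to {obs.n_alive} on day {obs.day}"
                )
            if obs.n_alive == 0 and obs.n_offspring != 0:
                raise CohortValidationError(
                    f"replicate {self.replicate_id!r}: offspring recorded with no "
                    f"survivors on day {obs.day}"
                )
            prev_day, prev_alive = obs.day, obs.n_alive

    @classmethod
    def from_rows(
        cls,
        replicate_id: str,
        initial_n: int,
        rows: Iterable[tuple[int, int, int]],
    ) -> "Cohort":
        """Build a cohort from (day, n_alive, n_offspring) triples."""
        obs = tuple(Observation(int(d), int(a), int(o)) for d, a, o in rows)
        return cls(replicate_id=replicate_id, initial_n=int(initial_n), observations=obs)


@dataclass(frozen=True)
class ScheduleRow:
    x: int
    l_x: float
    m_x: float


@dataclass(frozen=True)
class LifeTableSchedule:
    """Ordered (x, l_x, m_x) rows derived from one cohort."""

    rows: tuple[ScheduleRow, ...]

    def __post_init__(self) -> None:
        ages = [r.x for r in self.rows]
        if ages != sorted(set(ages)):
            raise CohortValidationError("schedule ages must be unique and increasing")
        prev = 1.0 + 1e-12
        for r in self.rows:
            if not (0.0 <= r.l_x <= prev):
                raise CohortValidationError(
                    f"l_x must be non-increasing within [0, 1]; violated at x={r.x}"
                )
            if not (math.isfinite(r.m_x) and r.m_x >= 0.0):
                raise CohortValidationError(f"m_x must be finite and >= 0 at x={r.x}")
            prev = r.l_x + 1e-12

    @property
    def ages(self) -> np.ndarray:
        return np.array([r.x for r in self.rows], dtype=float)

    @property
    def survival(self) -> np.ndarray:
        return np.array([r.l_x for r in self.rows], dtype=float)

    @property
    def fecundity(self) -> np.ndarray:
        return np.array([r.m_x for r in self.rows], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.ages.astype(int), "l_x": self.survival, "m_x": self.fecundity}
        )


@dataclass(frozen=True)
class DemographicParams:
    """R0, T and r_m for one replicate (or one pooled treatment).

    ``defined`` is False when R0 = 0 (no reproduction): T and r_m are
    then ``None``, mirroring the em-dash entries of printed tables.
    """

    r0: float
    t: float | None
    rm: float | None
    defined: bool

    def rounded(self) -> tuple[float, float | None, float | None]:
        """Display rounding: 1 dp for R0 and T, 2 dp for r_m (half-up)."""
        if not self.defined:
            return round_half_up(self.r0, 1), None, None
        return (
            round_half_up(self.r0, 1),
            round_half_up(self.t, 1),
            round_half_up(self.rm, 2),
        )


@dataclass(frozen=True)
class TreatmentSummary:
    """Per-treatment aggregation: mean +/- sample SD of each parameter.

    R0 means include zero-reproduction replicates (their R0 is a real
    observed 0); T and r_m means cover only replicates where they are
    defined, with the exclusion count in ``n_undefined``.
    """

    label: str
    n_replicates: int
    n_undefined: int
    params: tuple[DemographicParams, ...]
    r0_mean: float
    r0_sd: float
    t_mean: float | None
    t_sd: float | None
    rm_mean: float | None
    rm_sd: float | None

    @property
    def r0_values(self) -> list[float]:
        return [p.r0 for p in self.params]

    @property
    def t_values(self) -> list[float]:
        return [p.t for p in self.params if p.defined]

    @property
    def rm_values(self) -> list[float]:
        return [p.rm for p in self.params if p.defined]


@dataclass(frozen=True)
class SurvivalSummary:
    """Mean +/- SD percent survival at one day across replicates."""

    day: int
    mean: float
    sd: float
    values: tuple[float, ...]


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def build_life_table(cohort: Cohort, fill_gaps: bool = True) -> LifeTableSchedule:
    """Convert daily cohort records into an (x, l_x, m_x) schedule.

    ``l_x = n_alive(x) / initial_n``; ``m_x = n_offspring(x) / n_alive(x)``
    when anyone is alive, else 0.  With ``fill_gaps`` (default) a skipped
    check day is filled by carrying the last ``n_alive`` forward with
    ``m_x = 0``, so the age axis is contiguous.
    """
    rows: list[ScheduleRow] = []
    prev_day = 0
    prev_alive = cohort.initial_n
    for obs in cohort.observations:
        if fill_gaps:
            for day in range(prev_day + 1, obs.day):
                rows.append(ScheduleRow(day, prev_alive / cohort.initial_n, 0.0))
        l_x = obs.n_alive / cohort.initial_n
        m_x = obs.n_offspring / obs.n_alive if obs.n_alive > 0 else 0.0
        rows.append(ScheduleRow(obs.day, l_x, m_x))
        prev_day, prev_alive = obs.day, obs.n_alive
    return LifeTableSchedule(tuple(rows))


# ---------------------------------------------------------------------------
# Demographic parameters
# ---------------------------------------------------------------------------

def net_reproductive_rate(schedule: LifeTableSchedule) -> float:
    """R0 = sum over ages of l_x * m_x (expected lifetime offspring)."""
    return float(np.sum(schedule.survival * schedule.fecundity))


def generation_time(schedule: LifeTableSchedule) -> float:
    """T = sum(x * l_x * m_x) / sum(l_x * m_x), the fecundity-weighted mean age.

    Raises :class:`UndefinedParameterError` when R0 = 0.
    """
    weights = schedule.survival * schedule.fecundity
    r0 = float(np.sum(weights))
    if r0 <= 0.0:
        raise UndefinedParameterError("generation time undefined: R0 = 0")
    return float(np.sum(schedule.ages * weights) / r0)


def intrinsic_rate_of_increase(r0: float, t: float) -> float:
    """r_m = ln(R0) / T, the per-day exponential growth rate.

    Positive iff R0 > 1, zero iff R0 = 1, negative iff R0 < 1.
    """
    if r0 <= 0.0:
        raise UndefinedParameterError("r_m undefined: R0 must be > 0")
    if t <= 0.0:
        raise UndefinedParameterError("r_m undefined: T must be > 0")
    return math.log(r0) / t


def demographic_parameters(schedule: LifeTableSchedule) -> DemographicParams:
    """All three parameters for one schedule, flagging the R0 = 0 case."""
    r0 = net_reproductive_rate(schedule)
    if r0 <= 0.0:
        return DemographicParams(r0=0.0, t=None, rm=None, defined=False)
    t = generation_time(schedule)
    rm = intrinsic_rate_of_increase(r0, t)
    return DemographicParams(r0=r0, t=t, rm=rm, defined=True)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    # sample SD (ddof=1); a single replicate has no spread -> SD 0
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def replicate_parameters(
    cohorts: Sequence[Cohort], label: str = "treatment"
) -> TreatmentSummary:
    """Per-replicate parameters, then mean +/- sample SD per parameter.

    Replicates with R0 = 0 contribute 0 to the R0 mean but are excluded
    from the T and r_m means; the number excluded is reported and logged.
    """
    if not cohorts:
        raise ValueError("replicate_parameters requires at least one cohort")
    params = tuple(demographic_parameters(build_life_table(c)) for c in cohorts)
    defined = [p for p in params if p.defined]
    n_undefined = len(params) - len(defined)
    if n_undefined:
        logger.info(
            "%s: %d of %d replicates had no reproduction (T, r_m excluded)",
            label, n_undefined, len(params),
        )
    r0_mean, r0_sd = _mean_sd([p.r0 for p in params])
    if defined:
        t_mean, t_sd = _mean_sd([p.t for p in defined])
        rm_mean, rm_sd = _mean_sd([p.rm for p in defined])
    else:
        t_mean = t_sd = rm_mean = rm_sd = None
    return TreatmentSummary(
        label=label,
        n_replicates=len(params),
        n_undefined=n_undefined,
        params=params,
        r0_mean=r0_mean,
        r0_sd=r0_sd,
        t_mean=t_mean,
        t_sd=t_sd,
        rm_mean=rm_mean,
        rm_sd=rm_sd,
    )


def pooled_parameters(cohorts: Sequence[Cohort]) -> DemographicParams:
    """Parameters from the treatment-pooled schedule (one "super-cohort").

    Per day: l_x = total alive / total initial, m_x = total offspring /
    total alive.  Printed r_m values in host-transfer tables are
    sometimes consistent with ln(mean R0)/mean T rather than the mean of
    per-replicate r_m; this mode makes the pooled reading available.
    """
    if not cohorts:
        raise ValueError("pooled_parameters requires at least one cohort")
    max_day = max(c.observations[-1].day for c in cohorts)
    init_all = sum(c.initial_n for c in cohorts)
    alive_tot = np.zeros(max_day + 1, dtype=int)
    off_tot = np.zeros(max_day + 1, dtype=int)
    for c in cohorts:
        offspring = {o.day: o.n_offspring for o in c.observations}
        for day in range(1, max_day + 1):
            alive_tot[day] += _alive_at(c, day) if day >= c.observations[0].day else c.initial_n
            off_tot[day] += offspring.get(day, 0)
    rows = tuple(
        ScheduleRow(
            day,
            alive_tot[day] / init_all,
            off_tot[day] / alive_tot[day] if alive_tot[day] > 0 else 0.0,
        )
        for day in range(1, max_day + 1)
    )
    return demographic_parameters(LifeTableSchedule(rows))


# ---------------------------------------------------------------------------
# Survival summaries
# ---------------------------------------------------------------------------

def _alive_at(cohort: Cohort, day: int) -> int:
    """n_alive at ``day``, carrying the last observation forward."""
    if day < cohort.observations[0].day:
        raise ValueError(
            f"replicate {cohort.replicate_id!r}: day {day} precedes first "
            f"observation (day {cohort.observations[0].day})"
        )
    alive = cohort.observations[0].n_alive
    for obs in cohort.observations:
        if obs.day > day:
            break
        alive = obs.n_alive
    return alive


def survival_percent(cohorts: Sequence[Cohort], day: int) -> SurvivalSummary:
    """Mean +/- SD percent of the initial cohort alive at ``day``.

    Per replicate: ``100 * n_alive(day) / initial_n``; days past a
    cohort's last check carry the last count forward.
    """
    if not cohorts:
        raise ValueError("survival_percent requires at least one cohort")
    values = tuple(100.0 * _alive_at(c, day) / c.initial_n for c in cohorts)
    mean, sd = _mean_sd(values)
    return SurvivalSummary(day=day, mean=mean, sd=sd, values=values)
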
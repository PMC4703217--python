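"""Life-table schedules and demographic parameters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aphidkit import (
    Cohort,
    CohortValidationError,
    UndefinedParameterError,
    build_life_table,
    demographic_parameters,
    generation_time,
    intrinsic_rate_of_increase,
    net_reproductive_rate,
    pooled_parameters,
    replicate_parameters,
    round_half_up,
    survival_percent,
)
from aphidkit.lifetable import LifeTableSchedule, ScheduleRow


def make_schedule(rows):
    return LifeTableSchedule(tuple(ScheduleRow(*r) for r in rows))


class TestBuildLifeTable:
    def test_hand_computed_schedule(self):
        c = Cohort.from_rows("r1", 2, [(1, 2, 0), (2, 2, 4), (3, 0, 0)])
        s = build_life_table(c)
        assert [(r.x, r.l_x, r.m_x) for r in s.rows] == [
            (1, 1.0, 0.0),
            (2, 1.0, 2.0),
            (3, 0.0, 0.0),
        ]

    def test_zero_reproduction_cohort_has_all_zero_m_x(self):
        c = Cohort.from_rows("r1", 10, [(1, 6, 0), (2, 2, 0), (3, 0, 0)])
        s = build_life_table(c)
        assert all(r.m_x == 0.0 for r in s.rows)

    def test_missing_day_carried_forward_with_zero_m_x(self):
        c = Cohort.from_rows("r1", 4, [(1, 4, 0), (3, 2, 2)])
        s = build_life_table(c)
        assert [(r.x, r.l_x, r.m_x) for r in s.rows] == [
            (1, 1.0, 0.0),
            (2, 1.0, 0.0),
            (3, 0.5, 1.0),
        ]

    @pytest.mark.parametrize(
        "rows, message",
        [
            ([(1, 3, 0), (2, 5, 0)], "increases"),
            ([(2, 5, 0), (1, 4, 0)], "strictly increasing"),
            ([(1, 5, 0), (2, 0, 3)], "no survivors"),
            ([(1, 12, 0)], "exceeds"),
        ],
    )
    def test_invariant_violations_name_the_day(self, rows, message):
        with pytest.raises(CohortValidationError, match=message):
            Cohort.from_rows("bad", 10, rows)

    def test_empty_observations_rejected(self):
        with pytest.raises(CohortValidationError, match="empty"):
            Cohort(replicate_id="r", initial_n=10, observations=())


class TestParameters:
    def test_r0_direct_summation(self):
        s = make_schedule([(1, 1.0, 0.0), (2, 1.0, 2.0), (3, 0.0, 0.0)])
        assert net_reproductive_rate(s) == pytest.approx(2.0)
        assert generation_time(s) == pytest.approx(2.0)

    def test_r0_single_row_and_zero_cases(self):
        assert net_reproductive_rate(make_schedule([(1, 1.0, 5.0)])) == 5.0
        zero = make_schedule([(1, 1.0, 0.0), (2, 0.5, 0.0)])
        assert net_reproductive_rate(zero) == 0.0
        with pytest.raises(UndefinedParameterError):
            generation_time(zero)

    def test_generation_time_degenerate_single_reproductive_day(self):
        s = make_schedule([(1, 1.0, 0.0), (2, 1.0, 0.0), (7, 0.5, 3.0)])
        assert generation_time(s) == pytest.approx(7.0)

    def test_rm_printed_host_transfer_values(self):
        # natal-host means round to the same 0.35 / 0.36 / 0.14 at 2 dp
        assert round_half_up(intrinsic_rate_of_increase(30.7, 9.9), 2) == 0.35
        assert round_half_up(intrinsic_rate_of_increase(19.4, 8.5), 2) == 0.35
        assert round_half_up(intrinsic_rate_of_increase(30.9, 9.6), 2) == 0.36
        assert round_half_up(intrinsic_rate_of_increase(6.1, 12.9), 2) == 0.14

    def test_rm_of_unit_r0_is_zero(self):
        assert intrinsic_rate_of_increase(1.0, 12.3) == 0.0

    def test_rm_undefined_for_zero_r0(self):
        with pytest.raises(UndefinedParameterError):
            intrinsic_rate_of_increase(0.0, 5.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.01, 1.0),
                st.floats(0.0, 10.0),
            ),
            min_size=1,
            max_size=15,
        )
    )
    def test_identity_against_brute_force_loop(self, raw):
        # l_x made non-increasing by cumulative minimum
        rows, lo = [], 1.0
        for day, (l, m) in enumerate(raw, start=1):
            lo = min(lo, l)
            rows.append((day, lo, m))
        s = make_schedule(rows)
        r0_loop = sum(l * m for _, l, m in rows)
        if r0_loop <= 0:
            return
        t_loop = sum(x * l * m for x, l, m in rows) / r0_loop
        rm = intrinsic_rate_of_increase(net_reproductive_rate(s), generation_time(s))
        assert rm == pytest.approx(math.log(r0_loop) / t_loop, rel=1e-12)
        # sign law
        assert (rm > 0) == (r0_loop > 1)
        assert (rm < 0) == (r0_loop < 1)
        # T bracketed by reproductive ages
        repro = [x for x, l, m in rows if l * m > 0]
        assert min(repro) <= t_loop <= max(repro)

    def test_negative_rm_admitted(self):
        # alternate-host transfers print negative growth rates (R0 < 1)
        assert intrinsic_rate_of_increase(0.3, 8.7) < 0


class TestAggregation:
    def test_identical_replicates_have_zero_sd(self):
        c = Cohort.from_rows("a", 2, [(1, 2, 0), (2, 2, 4), (3, 0, 0)])
        c2 = Cohort.from_rows("b", 2, [(1, 2, 0), (2, 2, 4), (3, 0, 0)])
        s = replicate_parameters([c, c2], "twins")
        assert s.r0_sd == s.t_sd == s.rm_sd == 0.0

    def test_zero_r0_replicates_excluded_from_t_and_rm(self):
        good = Cohort.from_rows("g", 2, [(1, 2, 0), (2, 2, 4), (3, 0, 0)])  # R0 = 2
        good2 = Cohort.from_rows("h", 2, [(1, 2, 0), (2, 2, 4), (3, 0, 0)])
        bad = Cohort.from_rows("z", 2, [(1, 2, 0), (2, 0, 0)])  # R0 = 0
        s = replicate_parameters([good, good2, bad], "mixed")
        assert s.r0_mean == pytest.approx(4.0 / 3.0)
        assert s.n_undefined == 1
        assert len(s.rm_values) == 2
        assert s.rm_mean == pytest.approx(math.log(2.0) / 2.0)

    def test_all_undefined_treatment_reports_none(self):
        bad = Cohort.from_rows("z", 5, [(1, 3, 0), (2, 0, 0)])
        s = replicate_parameters([bad], "sterile")
        assert s.r0_mean == 0.0 and s.t_mean is None and s.rm_mean is None

    def test_scale_invariance_of_parameters(self):
        rows = [(1, 8, 0), (2, 8, 16), (3, 4, 4), (4, 0, 0)]
        small = Cohort.from_rows("s", 8, rows)
        big = Cohort.from_rows("b", 16, [(d, 2 * a, 2 * o) for d, a, o in rows])
        ps = demographic_parameters(build_life_table(small))
        pb = demographic_parameters(build_life_table(big))
        assert ps.r0 == pytest.approx(pb.r0)
        assert ps.t == pytest.approx(pb.t)
        assert ps.rm == pytest.approx(pb.rm)

    def test_pooled_mode_matches_per_replicate_for_identical_cohorts(self):
        c = Cohort.from_rows("a", 2, [(1, 2, 0), (2, 2, 4), (3, 0, 0)])
        c2 = Cohort.from_rows("b", 2, [(1, 2, 0), (2, 2, 4), (3, 0, 0)])
        pooled = pooled_parameters([c, c2])
        per = replicate_parameters([c, c2], "x")
        assert pooled.r0 == pytest.approx(per.r0_mean)
        assert pooled.rm == pytest.approx(per.rm_mean)


class TestSurvivalPercent:
    def test_all_alive_gives_100_with_zero_sd(self):
        cohorts = [
            Cohort.from_rows(f"r{i}", 10, [(1, 10, 0), (2, 10, 0)]) for i in range(5)
        ]
        s = survival_percent(cohorts, 1)
        assert (s.mean, s.sd) == (100.0, 0.0)

    def test_hand_mean_across_replicates(self):
        a = Cohort.from_rows("a", 10, [(1, 10, 0), (2, 10, 0)])
        b = Cohort.from_rows("b", 10, [(1, 10, 0), (2, 5, 0)])
        assert survival_percent([a, b], 2).mean == pytest.approx(75.0)

    def test_single_replicate_sd_zero(self):
        a = Cohort.from_rows("a", 10, [(1, 7, 0)])
        s = survival_percent([a], 1)
        assert s.sd == 0.0 and s.mean == pytest.approx(70.0)

    def test_carry_forward_after_last_observation(self):
        a = Cohort.from_rows("a", 10, [(1, 10, 0), (2, 4, 0)])
        assert survival_percent([a], 9).mean == pytest.approx(40.0)

    def test_day_before_first_observation_errors(self):
        a = Cohort.from_rows("a", 10, [(3, 10, 0)])
        with pytest.raises(ValueError, match="precedes"):
            survival_percent([a], 1)

    def test_monotone_nonincreasing_over_days(self):
        a = Cohort.from_rows("a", 10, [(1, 9, 0), (2, 7, 0), (4, 3, 0), (6, 0, 0)])
        series = [survival_percent([a], d).mean for d in range(1, 8)]
        assert all(x >= y for x, y in zip(series, series[1:]))


def test_round_half_up_matches_printed_table_convention():
    assert round_half_up(76.47) == 76.0
    assert round_half_up(76.5) == 77.0
    assert round_half_up(0.345, 2) == 0.35
    assert round_half_up(-0.155, 2) == -0.16
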
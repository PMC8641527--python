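"""Markov engine: transition rows, cohort propagation, outcome valuation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import afscreen as afs
from afscreen.lifetables import LifeTable
from afscreen.markov import (
    LIVING_STATES,
    State,
    build_transition_row,
    median_survival,
    microsimulate,
    no_screening_arm,
    on_treatment_fraction,
    run_cohort,
    screening_arm,
    trace_outcomes,
    transition_matrix,
)
from afscreen.parameters import (PersistenceSchedule, TreatmentEffect, UtilitySet,
                                 default_parameters)


def flat_lifetable(q=0.0, start=55, terminal=110):
    ages = np.arange(start, terminal + 1)
    qs = np.full(ages.size, float(q))
    qs[-1] = 1.0
    return LifeTable(ages=ages, q_annual=qs, terminal_age=terminal)


class TestOnTreatmentFraction:
    def test_persistence_schedule(self):
        pers = PersistenceSchedule()
        arm = screening_arm()
        assert on_treatment_fraction(1, arm, pers) == 0.70
        assert on_treatment_fraction(2, arm, pers) == 0.60
        assert on_treatment_fraction(5, arm, pers) == 0.60

    def test_no_screening_af_untreated(self):
        pers = PersistenceSchedule()
        arm = no_screening_arm()
        for cycle in (1, 2, 10):
            assert on_treatment_fraction(cycle, arm, pers, State.AF) == 0.0

    def test_post_stroke_treated_from_onset_in_both_arms(self):
        pers = PersistenceSchedule()
        for arm in (screening_arm(), no_screening_arm()):
            assert on_treatment_fraction(7, arm, pers, State.ACUTE_STROKE) == 0.70
            assert on_treatment_fraction(7, arm, pers, State.POST_STROKE) == 0.60


class TestTransitionRows:
    def test_absorbing_rows_are_identity(self, params, lifetable):
        for s in (State.DEAD_STROKE_ACUTE, State.DEAD_POST_STROKE,
                  State.DEAD_BLEED, State.DEAD_AGE):
            row = build_transition_row(s, params, 70, 0.5, lifetable)
            expected = np.zeros(8)
            expected[s] = 1.0
            assert np.array_equal(row, expected)

    def test_untreated_af_complement(self, params):
        # with zero background mortality the stay probability is the Table-1
        # complement 1 - 0.0108 - 0.0013 = 0.9879
        lt = flat_lifetable(0.0)
        row = build_transition_row(State.AF, params, 60, 0.0, lt)
        assert row[State.AF] == pytest.approx(0.9879, abs=1e-12)
        assert row[State.DEAD_STROKE_ACUTE] == pytest.approx(0.0023)
        assert row[State.ACUTE_STROKE] == pytest.approx(0.0108 - 0.0023)
        assert row[State.ACUTE_BLEED] == pytest.approx(0.0013 - 0.0001)

    @given(st.sampled_from(list(State)), st.floats(55, 105), st.floats(0, 1))
    def test_rows_always_sum_to_one(self, state, age, frac):
        params = default_parameters()
        lt = flat_lifetable(0.04)
        row = build_transition_row(state, params, age, frac, lt)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)
        assert (row >= 0).all()

    def test_oversubscribed_row_raises(self, lifetable):
        params = default_parameters()
        bad = params.replace(events=dataclasses.replace(
            params.events, p_stroke=0.7, p_major_bleed=0.6, p_bleed_acute_death=0.0))
        with pytest.raises(afs.markov.ModelConsistencyError, match="AF"):
            build_transition_row(State.AF, bad, 60, 0.0, lifetable)

    def test_bleed_tunnel_returns_to_af(self, params):
        lt = flat_lifetable(0.1)
        row = build_transition_row(State.ACUTE_BLEED, params, 60, 0.0, lt)
        q = 1 - 0.9 ** 0.5
        assert row[State.DEAD_AGE] == pytest.approx(q)
        assert row[State.AF] == pytest.approx(1 - q)


class TestRunCohort:
    def test_null_dynamics_stays_in_af(self):
        params = default_parameters()
        null = params.replace(events=dataclasses.replace(
            params.events, p_stroke=0.0, p_stroke_acute_death=0.0,
            p_major_bleed=0.0, p_bleed_acute_death=0.0))
        lt = flat_lifetable(0.0)
        with pytest.warns(UserWarning, match="not extinct"):
            trace = run_cohort(null, screening_arm(), lt)
        assert trace.occupancy[-1, State.AF] == pytest.approx(1.0, abs=1e-12)

    def test_occupancy_conservation(self, params, lifetable):
        for arm in (screening_arm(), no_screening_arm()):
            trace = run_cohort(params, arm, lifetable)
            sums = trace.occupancy.sum(axis=1)
            assert np.abs(sums - 1.0).max() < 1e-10

    def test_absorbing_occupancy_non_decreasing(self, base_eval):
        for trace in (base_eval.case_trace, base_eval.base_trace):
            dead = trace.occupancy[:, 4:]
            assert (np.diff(dead, axis=0) >= -1e-12).all()

    def test_event_entries_accounted(self, base_eval):
        trace = base_eval.base_trace
        # total deaths across causes equal the final dead occupancy
        total_deaths = sum(trace.entries[k].sum() for k in
                           ("deaths_stroke_acute", "deaths_post_stroke",
                            "deaths_bleed", "deaths_age"))
        assert total_deaths == pytest.approx(trace.occupancy[-1, 4:].sum(), abs=1e-8)


class TestTraceOutcomes:
    def test_discount_factors(self, params):
        cyc = params.cycle
        assert cyc.discount_factor(0) == 1.0
        assert cyc.discount_factor(2) == pytest.approx(1 / 1.04, abs=1e-9)  # year 1

    def test_full_health_makes_qalys_equal_lys(self, params, lifetable):
        full = params.replace(utilities=UtilitySet(
            u_af=1.0, u_acute_stroke=1.0, u_post_stroke=1.0, u_major_bleed=1.0,
            d_bleed=0.0))
        arm = screening_arm()
        out = trace_outcomes(run_cohort(full, arm, lifetable), full, arm)
        assert out.total_qaly(True) == pytest.approx(out.total_ly(True), rel=1e-12)

    def test_qalys_bounded_by_lys(self, base_eval):
        for res in (base_eval.case, base_eval.base):
            assert res.qaly_disc <= res.ly_disc
            assert res.qaly_undisc <= res.ly_undisc

    def test_discounting_reduces_totals(self, base_eval):
        for res in (base_eval.case, base_eval.base):
            assert res.qaly_disc < res.qaly_undisc
            assert res.ly_disc < res.ly_undisc
            assert res.cost_disc < res.cost_undisc


class TestMedianSurvival:
    def test_certain_first_cycle_death(self):
        params = default_parameters()
        lt = flat_lifetable(1.0)
        trace = run_cohort(params, no_screening_arm(), lt)
        # deaths interpolated uniformly within the fatal cycle (the tiny excess
        # over 0.25 y is the surviving event-tunnel mass)
        assert median_survival(trace) == pytest.approx(0.25, abs=0.01)

    def test_unique_crossing_for_monotone_survival(self, base_eval):
        living = base_eval.base_trace.living()
        crossings = np.sum((living[:-1] > 0.5) & (living[1:] <= 0.5))
        assert crossings == 1

    def test_base_case_values(self, base_eval):
        assert median_survival(base_eval.base_trace) == pytest.approx(10.0, abs=0.25)
        assert median_survival(base_eval.case_trace) > median_survival(
            base_eval.base_trace)


class TestMicrosimulationOracle:
    """Individual-level simulation must agree with the cohort trace."""

    @pytest.mark.parametrize("arm_factory", [screening_arm, no_screening_arm])
    def test_occupancy_within_monte_carlo_error(self, params, lifetable, arm_factory):
        n = 100_000
        arm = arm_factory()
        trace = run_cohort(params, arm, lifetable)
        occ_mc = microsimulate(params, arm, lifetable, n,
                               np.random.default_rng(2024), n_cycles=40)
        for cycle in (1, 10, 40):
            p = trace.occupancy[cycle]
            se = np.sqrt(p * (1 - p) / n)
            diff = np.abs(occ_mc[cycle] - p)
            assert (diff <= 3 * se + 5e-5).all(), f"cycle {cycle}: {diff / (se + 1e-12)}"


def test_null_treatment_equalizes_arms(params, lifetable):
    """With unit multipliers and free treatment the arms are indistinguishable."""
    neutral = params.replace(
        effect=TreatmentEffect(rr_stroke=1.0, rr_bleed=1.0, rr_mortality=1.0),
        costs=dataclasses.replace(params.costs, c_noac=0.0, c_warfarin=0.0, c_inr=0.0),
    )
    arm_c, arm_b = screening_arm(), no_screening_arm()
    out_c = trace_outcomes(run_cohort(neutral, arm_c, lifetable), neutral, arm_c)
    out_b = trace_outcomes(run_cohort(neutral, arm_b, lifetable), neutral, arm_b)
    assert out_c.total_qaly(True) == pytest.approx(out_b.total_qaly(True), abs=1e-12)
    assert out_c.total_ly(True) == pytest.approx(out_b.total_ly(True), abs=1e-12)
    assert out_c.total_cost(True) == pytest.approx(out_b.total_cost(True), abs=1e-9)


def test_conditional_acute_death_reading(params):
    ev = dataclasses.replace(params.events, acute_death_conditional=True,
                             p_stroke_acute_death=0.213)
    lt = flat_lifetable(0.0)
    row = build_transition_row(State.AF, params.replace(events=ev), 60, 0.0, lt)
    assert row[State.DEAD_STROKE_ACUTE] == pytest.approx(0.0108 * 0.213)
    assert row[State.ACUTE_STROKE] == pytest.approx(0.0108 * (1 - 0.213))


def test_half_cycle_correction_trims_edge_accrual(params, lifetable):
    corrected = params.replace(cycle=dataclasses.replace(
        params.cycle, half_cycle_correction=True))
    arm = screening_arm()
    plain = trace_outcomes(run_cohort(params, arm, lifetable), params, arm)
    hcc = trace_outcomes(run_cohort(corrected, arm, lifetable), corrected, arm)
    assert hcc.total_ly(False) < plain.total_ly(False)
    # only the first and last cycles are reweighted
    assert plain.total_ly(False) - hcc.total_ly(False) == pytest.approx(
        0.5 * (plain.ly[0] + plain.ly[-1]))


def test_trace_export_has_all_columns(base_eval):
    df = base_eval.case_trace.to_frame()
    for col in ("cycle", "age", "AF", "POST_STROKE", "DEAD_AGE", "on_treatment",
                "new_strokes"):
        assert col in df.columns
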
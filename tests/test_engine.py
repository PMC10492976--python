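"""Paired microsimulation: common random numbers, aggregation, subgroups."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from produce_rx.engine import (
    COST_CATEGORIES,
    SimulationParams,
    aggregate,
    incremental_person_totals,
    ledger_long_frame,
    mean_followup_years,
    run_paired,
    subgroup_aggregate,
)


@pytest.fixture(scope="module")
def short_params(base_params):
    return replace(base_params, max_cycles=20)


@pytest.fixture(scope="module")
def null_params(short_params):
    return short_params.scaled_effects(0.0)


@pytest.fixture(scope="module")
def base_run(cohort_2k, short_params):
    return run_paired(cohort_2k, short_params, seed=21)


@pytest.fixture(scope="module")
def null_run(cohort_2k, null_params):
    return run_paired(cohort_2k, null_params, seed=21)


def _arm_arrays(led):
    yield from [led.alive_end, led.first_chd, led.first_stroke, led.recurrent,
                led.cvd_death, led.other_death, led.utility]
    yield from led.costs.values()


class TestCommonRandomNumbers:
    def test_null_effects_make_health_paths_identical(self, null_run):
        """With zero effect deltas the arms share every health event and
        utility value exactly (not just in expectation)."""
        c, p = null_run.control, null_run.policy
        np.testing.assert_array_equal(c.alive_end, p.alive_end)
        np.testing.assert_array_equal(c.first_chd, p.first_chd)
        np.testing.assert_array_equal(c.first_stroke, p.first_stroke)
        np.testing.assert_array_equal(c.recurrent, p.recurrent)
        np.testing.assert_array_equal(c.utility, p.utility)
        np.testing.assert_array_equal(c.costs["healthcare"], p.costs["healthcare"])

    def test_null_effects_zero_incremental_variance(self, null_run):
        inc, _ = incremental_person_totals(null_run, "lifetime")
        for key in ("qalys", "total_events", "cost_healthcare", "cost_acute_event"):
            assert np.all(inc[key] == 0.0)

    def test_determinism_under_fixed_seed(self, cohort_500, short_params):
        a = run_paired(cohort_500, short_params, seed=3)
        b = run_paired(cohort_500, short_params, seed=3)
        for x, y in zip(_arm_arrays(a.policy), _arm_arrays(b.policy)):
            np.testing.assert_array_equal(x, y)

    def test_different_seeds_differ(self, cohort_500, short_params):
        a = run_paired(cohort_500, short_params, seed=3)
        b = run_paired(cohort_500, short_params, seed=4)
        assert not np.array_equal(a.control.alive_end, b.control.alive_end)


class TestProtectiveEffects:
    def test_policy_arm_averts_events(self, base_run):
        agg = aggregate(base_run, "lifetime")
        assert agg["first_events_averted"] > 0
        assert agg["total_events_averted"] > 0
        assert agg["qalys_gained"] > 0

    def test_policy_arm_first_events_never_exceed_control(self, base_run):
        """Rate-scale protective RRs with shared uniforms imply per-person
        first-event draws can only be averted, never induced."""
        pol = base_run.policy.first_event.sum()
        ctl = base_run.control.first_event.sum()
        assert pol <= ctl

    def test_dose_response_monotone_in_effect_scale(self, cohort_2k, short_params):
        qalys = []
        for lam in (0.0, 1.0, 2.0):
            run = run_paired(cohort_2k, short_params.scaled_effects(lam), seed=21)
            qalys.append(aggregate(run, "lifetime")["qalys_gained"])
        assert qalys[0] == pytest.approx(0.0, abs=1e-9)
        assert qalys[0] <= qalys[1] <= qalys[2]


class TestLedgerInvariants:
    def test_death_is_absorbing(self, base_run):
        for led in (base_run.control, base_run.policy):
            alive = led.alive_end.astype(int)
            assert np.all(np.diff(alive, axis=1) <= 0)

    def test_no_accrual_after_death(self, base_run):
        led = base_run.control
        dead = ~led.alive_start
        assert np.all(led.utility[dead] == 0.0)
        for cat in COST_CATEGORIES:
            assert np.all(led.costs[cat][dead] == 0.0)

    def test_first_events_at_most_once_per_person(self, base_run):
        for led in (base_run.control, base_run.policy):
            assert led.first_event.sum(axis=1).max() <= 1

    def test_recurrent_requires_prior_history(self, base_run, cohort_2k):
        led = base_run.control
        base_cvd = cohort_2k["cvd_history"].to_numpy(dtype=bool)
        first_cum = np.cumsum(led.first_event, axis=1).astype(bool)
        # history at cycle start: baseline or a first event in a prior cycle
        hist_start = np.concatenate(
            [base_cvd[:, None], base_cvd[:, None] | first_cum[:, :-1]], axis=1
        )
        assert np.all(hist_start[led.recurrent])

    def test_control_arm_has_no_intervention_costs(self, base_run):
        assert np.all(base_run.control.costs["intervention_food"] == 0.0)
        assert np.all(base_run.control.costs["intervention_admin"] == 0.0)

    def test_utilities_bounded(self, base_run):
        for led in (base_run.control, base_run.policy):
            assert np.all((led.utility >= 0.0) & (led.utility <= 1.0))


class TestAggregation:
    def test_total_equals_first_plus_recurrent(self, base_run):
        agg = aggregate(base_run, "lifetime")
        assert agg["total_events_averted"] == pytest.approx(
            agg["first_events_averted"] + agg["recurrent_events_averted"], abs=1e-9
        )

    def test_weighting_scales_population_totals(self, cohort_500, short_params):
        run = run_paired(cohort_500, short_params, seed=6)
        doubled = cohort_500.copy()
        doubled["survey_weight"] = 2 * doubled["survey_weight"]
        run2 = run_paired(doubled, short_params, seed=6)
        a, b = aggregate(run, "lifetime"), aggregate(run2, "lifetime")
        assert b["total_events_averted"] == pytest.approx(2 * a["total_events_averted"])
        assert b["qalys_gained"] == pytest.approx(2 * a["qalys_gained"])

    def test_single_averted_event_counts_its_weight(self, base_run, cohort_2k):
        """Population events averted equal the weighted sum of per-person
        averted counts (bookkeeping oracle)."""
        inc, w = incremental_person_totals(base_run, "lifetime")
        manual = float(np.sum(w * -inc["total_events"]))
        assert aggregate(base_run, "lifetime")["total_events_averted"] == pytest.approx(manual)

    def test_net_cost_perspectives(self, base_run):
        agg = aggregate(base_run, "lifetime")
        assert agg["net_cost_healthcare"] == pytest.approx(
            agg["intervention_cost_total"] - agg["healthcare_savings"], abs=1e-6
        )
        assert agg["net_cost_societal"] == pytest.approx(
            agg["net_cost_healthcare"] - agg["productivity_savings"], abs=1e-6
        )

    def test_horizon_beyond_simulation_rejected(self, base_run):
        with pytest.raises(ValueError, match="exceeds"):
            aggregate(base_run, 25)  # run only simulated 20 cycles

    def test_unknown_horizon_name_rejected(self, base_run):
        with pytest.raises(ValueError, match="horizon"):
            aggregate(base_run, "15y")

    def test_mean_followup_positive(self, base_run):
        assert 0 < mean_followup_years(base_run) <= base_run.max_cycles


class TestSubgroups:
    def test_sex_strata_sum_to_overall(self, base_run):
        overall = aggregate(base_run, "lifetime")
        strata = subgroup_aggregate(base_run, "sex", "lifetime")
        assert len(strata) == 2
        for key in ("total_events_averted", "qalys_gained", "net_cost_healthcare", "weight_total"):
            assert strata[key].sum() == pytest.approx(overall[key], rel=1e-9)

    def test_constant_stratifier_reproduces_overall(self, base_run):
        overall = aggregate(base_run, "lifetime")
        strata = subgroup_aggregate(base_run, "diabetes", "lifetime")
        assert len(strata) == 1
        assert strata["qalys_gained"].iloc[0] == pytest.approx(overall["qalys_gained"])

    def test_insurance_five_strata_conserve_weight(self, base_run, cohort_2k):
        strata = subgroup_aggregate(base_run, "insurance", "lifetime")
        assert len(strata) == 5
        assert strata["weight_total"].sum() == pytest.approx(cohort_2k["survey_weight"].sum())

    def test_unknown_stratifier_rejected(self, base_run):
        with pytest.raises(ValueError, match="stratifier"):
            subgroup_aggregate(base_run, "zodiac_sign", "lifetime")


class TestParticipation:
    def test_half_participation_enrolls_roughly_half(self, cohort_2k, short_params):
        params = replace(short_params, participation_fraction=0.5)
        run = run_paired(cohort_2k, params, seed=9)
        frac = run.participants.mean()
        assert 0.45 < frac < 0.55

    def test_nonparticipants_follow_control_trajectory(self, cohort_2k, short_params):
        params = replace(short_params, participation_fraction=0.5)
        run = run_paired(cohort_2k, params, seed=9)
        out = ~run.participants
        np.testing.assert_array_equal(
            run.policy.alive_end[out], run.control.alive_end[out]
        )
        np.testing.assert_array_equal(
            run.policy.utility[out], run.control.utility[out]
        )


class TestLedgerExport:
    def test_long_frame_shape_and_columns(self, cohort_500, short_params):
        run = run_paired(cohort_500, short_params, seed=2)
        frame = ledger_long_frame(run, horizon=5)
        assert set(frame["arm"].unique()) == {"control", "policy"}
        assert {"person_id", "year", "state", "utility"} <= set(frame.columns)
        assert set(frame["state"].unique()) <= {"no_cvd", "cvd_history", "dead"}
        assert frame["year"].max() == 5
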
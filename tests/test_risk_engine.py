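"""Transition probabilities, diet-disease relative risks, trajectories."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from produce_rx import (
    ConfigurationError,
    DietDiseaseRR,
    InterventionEffects,
    MortalityTable,
    RiskEquation,
    TrajectoryRules,
    adjust_probability,
    annual_probability,
    rr_from_delta,
    update_risk_factors,
)
from produce_rx.risk_engine import attenuation_for_age, risk_factor_state

from conftest import make_individual


def make_equation(intercept=0.0, **coeffs):
    base = {"age": 0.0, "male": 0.0, "bmi": 0.0, "hba1c": 0.0, "hypertension": 0.0}
    base.update(coeffs)
    return RiskEquation(
        outcome="first_chd",
        intercept=intercept,
        coefficients=base,
        race_offsets={},
        references={"age": 60.0, "bmi": 30.0, "hba1c": 7.0},
    )


class TestAnnualProbability:
    def test_zero_equation_gives_half(self):
        assert annual_probability(make_individual(), make_equation()) == pytest.approx(0.5)

    def test_saturation_at_large_negative_intercept(self):
        p = annual_probability(make_individual(), make_equation(intercept=-50.0))
        assert p < 1e-20

    def test_matches_manual_arithmetic(self):
        eq = make_equation(intercept=-4.0, age=0.07, male=0.3, bmi=0.04, hba1c=0.1, hypertension=0.4)
        rec = make_individual(age=65.0, sex="male", bmi=34.0, hba1c=8.2, hypertension=True)
        lp = -4.0 + 0.07 * (65 - 60) + 0.3 + 0.04 * (34 - 30) + 0.1 * (8.2 - 7) + 0.4
        expected = 1.0 / (1.0 + math.exp(-lp))
        assert annual_probability(rec, eq) == pytest.approx(expected, abs=1e-12)

    def test_missing_coefficient_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="missing coefficients"):
            RiskEquation(
                outcome="first_chd",
                intercept=0.0,
                coefficients={"age": 0.1},
                race_offsets={},
                references={"age": 60.0, "bmi": 30.0, "hba1c": 7.0},
            )

    def test_unknown_race_offset_is_configuration_error(self):
        eq = RiskEquation(
            outcome="first_chd",
            intercept=0.0,
            coefficients={"age": 0, "male": 0, "bmi": 0, "hba1c": 0, "hypertension": 0},
            race_offsets={"NH-White": 0.0},
            references={"age": 60.0, "bmi": 30.0, "hba1c": 7.0},
        )
        with pytest.raises(ConfigurationError, match="race offset"):
            annual_probability(make_individual(race_ethnicity="Hispanic"), eq)

    def test_default_equations_give_plausible_rates(self):
        """First-CVD ~1-3%/yr and recurrent ~3-6%/yr near the cohort centre."""
        rec = make_individual(age=58.0, bmi=33.6, hba1c=7.3, hypertension=True)
        p_chd = annual_probability(rec, RiskEquation.from_config("first_chd"))
        p_str = annual_probability(rec, RiskEquation.from_config("first_stroke"))
        p_first = 1 - (1 - p_chd) * (1 - p_str)
        assert 0.01 < p_first < 0.03
        p_rec = annual_probability(rec, RiskEquation.from_config("recurrent_cvd"))
        assert 0.03 < p_rec < 0.06

    def test_lower_risk_factors_never_increase_probability(self):
        eq = RiskEquation.from_config("first_chd")
        rec_hi = make_individual(bmi=36.0, hba1c=9.0)
        rec_lo = make_individual(bmi=35.64, hba1c=8.37)
        assert annual_probability(rec_lo, eq) < annual_probability(rec_hi, eq)


class TestRelativeRisk:
    def test_null_change_gives_null_rr(self):
        assert rr_from_delta(0.0, 0.95, 1.0) == pytest.approx(1.0)

    def test_log_linearity(self):
        assert rr_from_delta(2.0, 0.95, 1.0) == pytest.approx(0.95**2)

    def test_attenuated_evaluation(self):
        expected = math.exp(0.5 * 0.80 * math.log(0.95))
        assert rr_from_delta(0.80, 0.95, 0.5) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9797, abs=1e-4)

    @settings(deadline=None)
    @given(
        a=st.floats(-3, 3),
        b=st.floats(-3, 3),
        att=st.floats(0.1, 1.0),
    )
    def test_composition_in_delta(self, a, b, att):
        lhs = rr_from_delta(a + b, 0.95, att)
        rhs = rr_from_delta(a, 0.95, att) * rr_from_delta(b, 0.95, att)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            rr_from_delta(1.0, 0.0)

    def test_attenuation_bands(self):
        bands = DietDiseaseRR.from_config().age_attenuation_bands
        att = attenuation_for_age([50, 60, 70, 80], bands)
        assert att[0] == 1.0
        assert np.all(np.diff(att) < 0)  # attenuates toward the null with age


class TestAdjustProbability:
    def test_zero_risk_preserved(self):
        assert adjust_probability(0.0, 0.5) == 0.0

    def test_null_rr_identity(self):
        assert adjust_probability(0.123, 1.0) == pytest.approx(0.123)

    def test_closed_form_value(self):
        assert adjust_probability(0.10, 0.5) == pytest.approx(1 - 0.9**0.5, abs=1e-12)
        assert adjust_probability(0.10, 0.5) == pytest.approx(0.05132, abs=1e-5)

    def test_first_order_agreement_with_multiplicative(self):
        p = 1e-6
        for rr in (0.5, 0.9, 1.5):
            assert abs(adjust_probability(p, rr) - p * rr) < 1e-8

    @settings(deadline=None)
    @given(p=st.floats(0, 1), rr=st.floats(0.01, 5.0))
    def test_stays_in_unit_interval(self, p, rr):
        out = adjust_probability(p, rr)
        assert 0.0 <= out <= 1.0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            adjust_probability(1.2, 0.5)


class TestTrajectories:
    def setup_method(self):
        self.deltas = InterventionEffects.from_config().deltas()
        self.rules = TrajectoryRules()

    def test_enrolled_effect_passthrough_on_diet_total(self):
        rec = make_individual(fruit_servings=0.86, veg_servings=1.30)
        out = update_risk_factors(rec, 1, self.rules, True, self.deltas)
        assert out["fruit_servings"] + out["veg_servings"] == pytest.approx(2.96, abs=1e-12)
        assert out["bmi"] == pytest.approx(rec["bmi"] - 0.36)
        assert out["hba1c"] == pytest.approx(rec["hba1c"] - 0.63)

    def test_not_enrolled_only_age_advances(self):
        rec = make_individual()
        out = update_risk_factors(rec, 3, self.rules, False, self.deltas)
        assert out["age"] == rec["age"] + 3
        for key in ("bmi", "hba1c", "fruit_servings", "veg_servings"):
            assert out[key] == pytest.approx(rec[key])

    def test_benefits_cease_on_exit(self):
        rec = make_individual()
        enrolled_then_exit = update_risk_factors(rec, 2, self.rules, False, self.deltas)
        never = update_risk_factors(rec, 2, self.rules, False, self.deltas)
        assert enrolled_then_exit == never

    def test_zero_diet_baseline_splits_delta_evenly(self):
        rec = make_individual(fruit_servings=0.0, veg_servings=0.0)
        out = update_risk_factors(rec, 1, self.rules, True, self.deltas)
        assert out["fruit_servings"] == pytest.approx(0.40)
        assert out["veg_servings"] == pytest.approx(0.40)

    def test_secular_drift_accrues_linearly(self):
        rules = TrajectoryRules(bmi_drift=0.1)
        rec = make_individual(bmi=30.0)
        out = update_risk_factors(rec, 5, rules, False, self.deltas)
        assert out["bmi"] == pytest.approx(30.5)

    def test_year_index_must_be_positive(self):
        with pytest.raises(ValueError):
            risk_factor_state(pd.DataFrame([make_individual()]), 0, self.rules, False, self.deltas)


class TestMortalityTable:
    def test_default_table_monotone_in_age(self):
        table = MortalityTable.from_config()
        q60 = table.probability(60, True)
        q80 = table.probability(80, True)
        assert 0 < q60 < q80 < 1

    def test_female_rates_below_male(self):
        table = MortalityTable.from_config()
        assert table.probability(70, False) < table.probability(70, True)

    def test_age_clamped_to_table_range(self):
        table = MortalityTable.from_config()
        assert table.probability(130, True) == table.probability(110, True)

    def test_csv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [(a, s, q) for a, s, q in [(40, "female", 0.001), (40, "male", 0.002),
                                       (41, "female", 0.0011), (41, "male", 0.0022)]],
            columns=["age", "sex", "annual_probability"],
        )
        path = tmp_path / "mort.csv"
        df.to_csv(path, index=False)
        table = MortalityTable.from_csv(path)
        assert table.probability(41, True) == pytest.approx(0.0022)

    def test_invalid_probability_rejected(self):
        df = pd.DataFrame(
            [(40, "female", 1.5), (40, "male", 0.002)],
            columns=["age", "sex", "annual_probability"],
        )
        with pytest.raises(ConfigurationError):
            MortalityTable.from_frame(df)
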
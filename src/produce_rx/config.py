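"""Default parameter sets and configuration handling.

All tunable inputs of the model live in a single nested dictionary with
sections ``population``, ``effects``, ``diet_rr``, ``risk_equations``,
``mortality_table``, ``costs``, ``utilities``, ``scenario`` and ``cea``.
Users may override any subset through a YAML/JSON file; values not given
fall back to the defaults below.

The population section carries the published baseline marginals of the
eligible cohort (US adults 40-79 with diabetes and food insecurity).  The
risk-equation, cost-regression, utility-regression and mortality defaults
are synthetic stand-ins calibrated to plausible US rates for this
high-risk population; they are structural placeholders meant to be
overridden with fitted coefficients when available.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration section is malformed or incomplete."""


# ---------------------------------------------------------------------------
# Population (baseline-characteristics marginals of the eligible cohort)
# ---------------------------------------------------------------------------

POPULATION_DEFAULTS: dict[str, Any] = {
    # survey-weighted national population represented by the cohort
    "total_population": 6_500_000,
    # lognormal sigma for the synthetic survey weights (mu fixed at 0,
    # weights rescaled to sum to total_population)
    "weight_sigma": 0.5,
    "continuous": {
        "age": {"mean": 58.2, "sd": 10.2, "lower": 40.0, "upper": 79.0},
        "bmi": {"mean": 33.6, "sd": 7.95, "lower": 15.0, "upper": 70.0},
        "hba1c": {"mean": 7.3, "sd": 1.95, "lower": 4.5, "upper": 18.0},
        "fruit_servings": {"mean": 0.86, "sd": 1.08, "lower": 0.0, "upper": 12.0, "family": "gamma"},
        "veg_servings": {"mean": 1.30, "sd": 1.04, "lower": 0.0, "upper": 12.0, "family": "gamma"},
    },
    # latent-scale correlations between continuous variables (Gaussian
    # copula); unlisted pairs are independent
    "correlations": [["bmi", "hba1c", 0.2]],
    "categorical": {
        "sex": {"female": 0.556, "male": 0.444},
        "race_ethnicity": {
            "NH-White": 0.431,
            "NH-Black": 0.172,
            "Hispanic": 0.290,
            "Other": 0.107,
        },
        "education": {"<HS": 0.371, "HS/GED": 0.265, "some-college+": 0.364},
        "income_poverty_ratio": {
            "<1.30": 0.566,
            "1.30-1.84": 0.171,
            "1.85-2.99": 0.164,
            ">3.00": 0.099,
        },
    },
    # Published insurance percentages overlap (sum 112.2%) because dual
    # eligibility overlaps the Medicare/Medicaid rows in the source table;
    # the generator renormalizes these to a proper distribution.
    "insurance_raw_percent": {
        "private": 29.4,
        "medicare": 26.9,
        "medicaid": 26.9,
        "dual": 12.5,
        "none": 16.5,
    },
    "hypertension": 0.748,
    "cvd": {
        "prevalence": 0.300,
        # log-odds increase in CVD-history probability per year of age;
        # the intercept is calibrated so the marginal prevalence holds
        "age_log_odds_slope": 0.06,
        "subflags": {"angina": 0.158, "chd": 0.119, "mi": 0.128, "stroke": 0.091},
    },
}


# ---------------------------------------------------------------------------
# Pooled intervention effects (meta-analysis of produce prescription trials)
# ---------------------------------------------------------------------------

EFFECTS_DEFAULTS: dict[str, Any] = {
    "fv_servings": {"mean": 0.80, "ci_low": 0.45, "ci_high": 1.15},
    "bmi": {"mean": -0.36, "ci_low": -0.55, "ci_high": -0.16},
    "hba1c": {"mean": -0.63, "ci_low": -0.98, "ci_high": -0.28},
    "participation_fraction": 1.0,
    "persistence": "benefits_cease_on_exit",
}


# ---------------------------------------------------------------------------
# Diet-disease relative risks (log-linear per +1 serving/day F&V)
# ---------------------------------------------------------------------------

DIET_RR_DEFAULTS: dict[str, Any] = {
    "rr_chd_per_serving": 0.95,
    "rr_stroke_per_serving": 0.96,
    # PSA standard errors on the log-RR scale
    "log_rr_se": {"chd": 0.015, "stroke": 0.012},
    # [age_low, age_high, multiplier] bands scaling the log-RR toward 0
    # (i.e. RR toward 1) at older ages
    "age_attenuation_bands": [
        [0.0, 55.0, 1.00],
        [55.0, 65.0, 0.85],
        [65.0, 75.0, 0.70],
        [75.0, 200.0, 0.55],
    ],
    # CHD share used when pooling CHD/stroke quantities for recurrent events
    "recurrent_chd_weight": 0.6,
}


# ---------------------------------------------------------------------------
# Annual transition-probability equations (logistic link).  Synthetic
# stand-ins: intercepts target first-CVD ~1-3%/yr and recurrent ~3-6%/yr
# in this population; covariates are centred at the listed references.
# ---------------------------------------------------------------------------

RISK_EQUATION_DEFAULTS: dict[str, Any] = {
    "references": {"age": 60.0, "bmi": 30.0, "hba1c": 7.0},
    "first_chd": {
        "intercept": -4.55,
        "coefficients": {
            "age": 0.065,
            "male": 0.35,
            "bmi": 0.035,
            "hba1c": 0.10,
            "hypertension": 0.35,
        },
        "race_offsets": {"NH-White": 0.0, "NH-Black": 0.15, "Hispanic": 0.08, "Other": 0.0},
    },
    "first_stroke": {
        "intercept": -5.10,
        "coefficients": {
            "age": 0.075,
            "male": 0.18,
            "bmi": 0.02,
            "hba1c": 0.09,
            "hypertension": 0.50,
        },
        "race_offsets": {"NH-White": 0.0, "NH-Black": 0.25, "Hispanic": 0.08, "Other": 0.0},
    },
    "recurrent_cvd": {
        "intercept": -3.10,
        "coefficients": {
            "age": 0.05,
            "male": 0.20,
            "bmi": 0.02,
            "hba1c": 0.08,
            "hypertension": 0.20,
        },
        "race_offsets": {"NH-White": 0.0, "NH-Black": 0.10, "Hispanic": 0.05, "Other": 0.0},
    },
    "cvd_death": {
        "intercept": -3.90,
        "coefficients": {
            "age": 0.085,
            "male": 0.25,
            "bmi": 0.01,
            "hba1c": 0.05,
            "hypertension": 0.15,
        },
        "race_offsets": {"NH-White": 0.0, "NH-Black": 0.10, "Hispanic": 0.0, "Other": 0.0},
    },
}

# Synthetic non-CVD mortality table: Gompertz-shaped annual probabilities
# q(age) = c * exp(b * age), elevated relative to the general population to
# reflect diabetes, capped at 0.95.  Female rates are 65% of male rates.
MORTALITY_DEFAULTS: dict[str, Any] = {
    "gompertz": {"male_c": 5.4e-5, "male_b": 0.09, "female_ratio": 0.65, "cap": 0.95},
    "age_min": 40,
    "age_max": 110,
    # when set, overrides the Gompertz default: list of [age, sex, q]
    "table": None,
}


# ---------------------------------------------------------------------------
# Costs (2021 USD) and health-related quality of life
# ---------------------------------------------------------------------------

COSTS_DEFAULTS: dict[str, Any] = {
    "monthly_offered": 42.0,
    "monthly_redeemed": 32.0,
    "admin_share_steady": 0.15,
    "admin_share_presets": {"snap_high": 0.08, "wic": 0.213, "wic_sensitivity": 0.23},
    "acute_cost_chd": 21000.0,
    "acute_cost_stroke": 17500.0,
    "productivity_chd": 1100.0,
    "productivity_stroke": 1700.0,
    # $/year per HbA1c point above the reference, non-CVD diabetes costs only
    "hba1c_cost_slope": 1150.0,
    "hba1c_cost_reference": 7.0,
    "discount_rate": 0.03,
    "currency_year": 2021,
    # Expenditure-survey-style annual healthcare cost regression (synthetic stand-in)
    "healthcare_regression": {
        "intercept": 4200.0,
        "coefficients": {
            "age": 85.0,
            "male": -250.0,
            "bmi": 55.0,
            "hypertension": 1400.0,
            "cvd_history": 6200.0,
            "diabetes": 2900.0,
        },
        "race_offsets": {"NH-White": 0.0, "NH-Black": -150.0, "Hispanic": -400.0, "Other": -250.0},
        "references": {"age": 60.0, "bmi": 30.0},
    },
    # PSA: relative standard error applied to sampled cost parameters
    "psa_relative_se": 0.10,
}

UTILITIES_DEFAULTS: dict[str, Any] = {
    "decrement_chd": 0.055,
    "decrement_stroke": 0.3,
    # EQ-5D prediction regression (synthetic stand-in), clamped to [0, 1]
    "eq5d_regression": {
        "intercept": 0.922,
        "coefficients": {
            "age": -0.0022,
            "male": 0.006,
            "bmi": -0.0028,
            "hypertension": -0.018,
            "cvd_history": -0.072,
            "diabetes": -0.055,
        },
        "race_offsets": {"NH-White": 0.0, "NH-Black": -0.004, "Hispanic": -0.002, "Other": 0.0},
        "references": {"age": 60.0, "bmi": 30.0},
    },
    # PSA: absolute SE on the regression intercept and relative SE on decrements
    "psa_intercept_se": 0.01,
    "psa_decrement_relative_se": 0.10,
}


SCENARIO_DEFAULTS: dict[str, Any] = {
    "participation_fraction": 1.0,
    "max_cycles": 60,
    "horizons": {"5y": 5, "10y": 10, "lifetime": 60},
}

CEA_DEFAULTS: dict[str, Any] = {
    "wtp": [50000.0, 150000.0],
    "n_draws": 1000,
    "one_way_percentiles": [0.025, 0.10, 0.25, 0.50, 0.75, 0.90, 0.975],
    "threshold_wtp": 150000.0,
    "threshold_tolerance": 0.10,
}


def default_config() -> dict[str, Any]:
    """Return a deep copy of the full default configuration."""
    return copy.deepcopy(
        {
            "population": POPULATION_DEFAULTS,
            "effects": EFFECTS_DEFAULTS,
            "diet_rr": DIET_RR_DEFAULTS,
            "risk_equations": RISK_EQUATION_DEFAULTS,
            "mortality_table": MORTALITY_DEFAULTS,
            "costs": COSTS_DEFAULTS,
            "utilities": UTILITIES_DEFAULTS,
            "scenario": SCENARIO_DEFAULTS,
            "cea": CEA_DEFAULTS,
        }
    )


# the published base case is the default parameterization
PRESETS = {"base-case": default_config}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None, preset: str = "base-case") -> dict[str, Any]:
    """Load a configuration, merging a user YAML/JSON file over a preset.

    Parameters
    ----------
    path:
        Optional YAML or JSON file.  Only the keys present are overridden;
        everything else keeps its preset value.
    preset:
        Name of the base parameter bundle (currently ``base-case``).
    """
    if preset not in PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[preset]()
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            user = json.loads(text)
        else:
            user = yaml.safe_load(text)
        if user is None:
            user = {}
        if not isinstance(user, Mapping):
            raise ConfigurationError(f"config file {path} must contain a mapping at top level")
        cfg = _deep_merge(cfg, user)
    return cfg
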
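"""Costs and health-related quality of life.

Covers the four cost streams of the analysis — program (food + admin)
costs, annual individual healthcare costs with an HbA1c-dependent
non-CVD diabetes component, acute event costs, and productivity costs of
prevalent CHD/stroke — plus EQ-5D utility prediction with one-year acute
event decrements, and 3%/year discounting (first year undiscounted).

All monetary quantities are 2021 USD.  The healthcare-cost and EQ-5D
regressions shipped in the default config are synthetic stand-ins with
the published covariate structure (age, sex, race/ethnicity, BMI,
diabetes, hypertension, CVD history); override their coefficients with
fitted values for dollar-level work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .config import COSTS_DEFAULTS, UTILITIES_DEFAULTS, ConfigurationError

__all__ = [
    "CostParams",
    "UtilityParams",
    "intervention_cost",
    "annual_healthcare_cost",
    "annual_utility",
    "productivity_cost",
    "discount",
    "discount_factors",
]

_REGRESSION_COVARIATES = ("age", "male", "bmi", "hypertension", "cvd_history", "diabetes")


@dataclass
class CostParams:
    monthly_offered: float = 42.0
    monthly_redeemed: float = 32.0
    admin_share_steady: float = 0.15
    acute_cost_chd: float = 21000.0
    acute_cost_stroke: float = 17500.0
    productivity_chd: float = 1100.0
    productivity_stroke: float = 1700.0
    hba1c_cost_slope: float = 1150.0
    hba1c_cost_reference: float = 7.0
    discount_rate: float = 0.03
    currency_year: int = 2021
    healthcare_regression: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "monthly_offered", "monthly_redeemed", "acute_cost_chd", "acute_cost_stroke",
            "productivity_chd", "productivity_stroke", "hba1c_cost_slope",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if not 0.0 < self.admin_share_steady < 1.0:
            raise ConfigurationError("admin_share_steady must lie in (0, 1)")
        if not self.healthcare_regression:
            self.healthcare_regression = dict(COSTS_DEFAULTS["healthcare_regression"])

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any] | None = None) -> "CostParams":
        cfg = COSTS_DEFAULTS if cfg is None else cfg
        return cls(
            monthly_offered=float(cfg["monthly_offered"]),
            monthly_redeemed=float(cfg["monthly_redeemed"]),
            admin_share_steady=float(cfg["admin_share_steady"]),
            acute_cost_chd=float(cfg["acute_cost_chd"]),
            acute_cost_stroke=float(cfg["acute_cost_stroke"]),
            productivity_chd=float(cfg["productivity_chd"]),
            productivity_stroke=float(cfg["productivity_stroke"]),
            hba1c_cost_slope=float(cfg["hba1c_cost_slope"]),
            hba1c_cost_reference=float(cfg["hba1c_cost_reference"]),
            discount_rate=float(cfg["discount_rate"]),
            currency_year=int(cfg["currency_year"]),
            healthcare_regression=dict(cfg["healthcare_regression"]),
        )

    @property
    def annual_offered(self) -> float:
        return 12.0 * self.monthly_offered

    @property
    def annual_redeemed(self) -> float:
        return 12.0 * self.monthly_redeemed


@dataclass
class UtilityParams:
    decrement_chd: float = 0.055
    decrement_stroke: float = 0.3
    eq5d_regression: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.eq5d_regression:
            self.eq5d_regression = dict(UTILITIES_DEFAULTS["eq5d_regression"])

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any] | None = None) -> "UtilityParams":
        cfg = UTILITIES_DEFAULTS if cfg is None else cfg
        return cls(
            decrement_chd=float(cfg["decrement_chd"]),
            decrement_stroke=float(cfg["decrement_stroke"]),
            eq5d_regression=dict(cfg["eq5d_regression"]),
        )


def intervention_cost(year_index: int, params: CostParams) -> tuple[float, float]:
    """Per participating person-year program cost, split (food, admin).

    Food cost is the redeemed value (12 x monthly_redeemed).  In program
    year 1 the administrative cost equals 50% of food cost — a launch
    premium making admin one third of total cost — and thereafter the
    share ``s`` of total, i.e. admin = food * s / (1 - s), so that
    admin / (admin + food) = s exactly.
    """
    if year_index < 1:
        raise ValueError("year_index must be >= 1")
    food = params.annual_redeemed
    if year_index == 1:
        admin = 0.5 * food
    else:
        s = params.admin_share_steady
        admin = food * s / (1.0 - s)
    return food, admin


def _linear_regression(
    reg: Mapping[str, Any],
    age, male, bmi, hypertension, cvd_history, diabetes, race,
) -> np.ndarray:
    coeffs = reg["coefficients"]
    missing = [c for c in _REGRESSION_COVARIATES if c not in coeffs]
    if missing:
        raise ConfigurationError(f"regression is missing coefficients for {missing}")
    refs = reg.get("references", {})
    pred = (
        float(reg["intercept"])
        + coeffs["age"] * (np.asarray(age, dtype=float) - refs.get("age", 0.0))
        + coeffs["male"] * np.asarray(male, dtype=float)
        + coeffs["bmi"] * (np.asarray(bmi, dtype=float) - refs.get("bmi", 0.0))
        + coeffs["hypertension"] * np.asarray(hypertension, dtype=float)
        + coeffs["cvd_history"] * np.asarray(cvd_history, dtype=float)
        + coeffs["diabetes"] * np.asarray(diabetes, dtype=float)
    )
    offsets = reg.get("race_offsets", {})
    if offsets:
        race_arr = np.asarray(race, dtype=object)
        try:
            pred = pred + np.vectorize(offsets.__getitem__)(race_arr).astype(float)
        except KeyError as exc:
            raise ConfigurationError(f"regression has no race offset for {exc.args[0]!r}") from None
    return pred


def _covariate_arrays(individual: Mapping[str, Any] | pd.DataFrame) -> dict[str, Any]:
    if isinstance(individual, pd.DataFrame):
        get = lambda c: individual[c].to_numpy()
    else:
        get = lambda c: individual[c]
    return {
        "age": get("age"),
        "male": np.asarray(get("sex"), dtype=object) == "male",
        "bmi": get("bmi"),
        "hypertension": np.asarray(get("hypertension"), dtype=float),
        "cvd_history": np.asarray(get("cvd_history"), dtype=float),
        "diabetes": np.asarray(get("diabetes"), dtype=float),
        "race": get("race_ethnicity"),
    }


def annual_healthcare_cost(
    individual: Mapping[str, Any] | pd.DataFrame, params: CostParams
) -> float | np.ndarray:
    """Predicted annual healthcare cost for an individual (or cohort frame).

    Linear prediction over demographics, BMI, diabetes, hypertension and
    CVD history, plus ``hba1c_cost_slope * max(0, hba1c - reference)``.
    The HbA1c term models only the glycemia-dependent (non-CVD) diabetes
    costs: CVD-dependent costs enter solely through the CVD-history
    coefficient and the separate acute event costs, so lowering HbA1c
    cannot double-count averted CVD spending.  Predictions are floored
    at zero.
    """
    cov = _covariate_arrays(individual)
    pred = _linear_regression(
        params.healthcare_regression,
        cov["age"], cov["male"], cov["bmi"], cov["hypertension"],
        cov["cvd_history"], cov["diabetes"], cov["race"],
    )
    hba1c = (
        individual["hba1c"].to_numpy(dtype=float)
        if isinstance(individual, pd.DataFrame)
        else np.asarray(individual["hba1c"], dtype=float)
    )
    diabetic = np.asarray(cov["diabetes"], dtype=float)
    pred = pred + params.hba1c_cost_slope * diabetic * np.maximum(
        0.0, hba1c - params.hba1c_cost_reference
    )
    pred = np.maximum(pred, 0.0)
    return float(pred) if pred.ndim == 0 else pred


def annual_utility(
    individual: Mapping[str, Any] | pd.DataFrame,
    params: UtilityParams,
    acute_chd: bool | np.ndarray = False,
    acute_stroke: bool | np.ndarray = False,
) -> float | np.ndarray:
    """EQ-5D utility for the year, with one-year acute event decrements.

    The predicted utility loses 0.055 in a year with an acute CHD event
    and 0.3 in a year with an acute stroke, then is clamped to [0, 1].
    Decrements apply only in the event year.
    """
    cov = _covariate_arrays(individual)
    pred = _linear_regression(
        params.eq5d_regression,
        cov["age"], cov["male"], cov["bmi"], cov["hypertension"],
        cov["cvd_history"], cov["diabetes"], cov["race"],
    )
    pred = pred - params.decrement_chd * np.asarray(acute_chd, dtype=float)
    pred = pred - params.decrement_stroke * np.asarray(acute_stroke, dtype=float)
    pred = np.clip(pred, 0.0, 1.0)
    return float(pred) if pred.ndim == 0 else pred


def productivity_cost(
    individual: Mapping[str, Any] | pd.DataFrame,
    params: CostParams,
    chd_prevalent: np.ndarray | bool | None = None,
    stroke_prevalent: np.ndarray | bool | None = None,
) -> float | np.ndarray:
    """Annual productivity cost: per-prevalent-case values for CHD and
    stroke, additive when both are present, zero otherwise.

    Prevalence flags default to the record's CHD-type sub-flags
    (angina/chd/mi) and stroke sub-flag.
    """
    if chd_prevalent is None or stroke_prevalent is None:
        if isinstance(individual, pd.DataFrame):
            chd_prevalent = individual[["angina", "chd", "mi"]].astype(bool).any(axis=1).to_numpy()
            stroke_prevalent = individual["stroke"].astype(bool).to_numpy()
        else:
            chd_prevalent = bool(individual["angina"]) or bool(individual["chd"]) or bool(individual["mi"])
            stroke_prevalent = bool(individual["stroke"])
    cost = params.productivity_chd * np.asarray(chd_prevalent, dtype=float) + (
        params.productivity_stroke * np.asarray(stroke_prevalent, dtype=float)
    )
    return float(cost) if cost.ndim == 0 else cost


def discount(amount, year_index: int, rate: float):
    """Present value of ``amount`` accrued in ``year_index`` (year 1
    undiscounted): amount / (1 + rate)^(year_index - 1)."""
    if rate < 0:
        raise ValueError("discount rate must be nonnegative")
    if np.any(np.asarray(year_index) < 1):
        raise ValueError("year_index must be >= 1")
    return np.asarray(amount) / (1.0 + rate) ** (np.asarray(year_index) - 1)


def discount_factors(n_years: int, rate: float) -> np.ndarray:
    """Vector of present-value factors for years 1..n_years."""
    if rate < 0:
        raise ValueError("discount rate must be nonnegative")
    return (1.0 + rate) ** (-np.arange(n_years, dtype=float))
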
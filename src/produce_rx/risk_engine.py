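"""Annual transition probabilities and risk-factor trajectories.

Event probabilities (first CHD, first stroke, recurrent CVD, CVD death)
come from logistic annual-probability equations over age, sex,
race/ethnicity, BMI, HbA1c, hypertension; non-CVD mortality comes from an
age-sex annual-probability table.  Diet acts through a log-linear
relative risk per +1 serving/day of fruits and vegetables, attenuated
toward the null at older ages, applied to annual probabilities on the
rate scale (p' = 1 - (1-p)^RR).

Risk factors evolve deterministically from baseline: age advances one
year per cycle, optional secular drifts accrue linearly, and intervention
deltas are level shifts present exactly while enrolled (benefits cease on
exit), so a disenrolled person's trajectory coincides with the
never-enrolled one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    DIET_RR_DEFAULTS,
    MORTALITY_DEFAULTS,
    RISK_EQUATION_DEFAULTS,
    ConfigurationError,
)

__all__ = [
    "RiskEquation",
    "DietDiseaseRR",
    "TrajectoryRules",
    "MortalityTable",
    "annual_probability",
    "rr_from_delta",
    "adjust_probability",
    "attenuation_for_age",
    "update_risk_factors",
    "risk_factor_state",
]

EQUATION_OUTCOMES = ("first_chd", "first_stroke", "recurrent_cvd", "cvd_death")

_REQUIRED_COEFFS = ("age", "male", "bmi", "hba1c", "hypertension")


@dataclass(frozen=True)
class RiskEquation:
    """Logistic annual-probability equation.

    The linear predictor is
    ``intercept + b_age*(age-ref) + b_male*male + b_bmi*(bmi-ref)
    + b_hba1c*(hba1c-ref) + b_htn*htn + race_offset`` and the annual
    probability its inverse logit.
    """

    outcome: str
    intercept: float
    coefficients: dict[str, float]
    race_offsets: dict[str, float]
    references: dict[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COEFFS if c not in self.coefficients]
        if missing:
            raise ConfigurationError(
                f"risk equation {self.outcome!r} is missing coefficients for {missing}"
            )

    @classmethod
    def from_config(cls, outcome: str, cfg: Mapping[str, Any] | None = None) -> "RiskEquation":
        cfg = RISK_EQUATION_DEFAULTS if cfg is None else cfg
        if outcome not in cfg:
            raise ConfigurationError(f"no risk equation configured for outcome {outcome!r}")
        eq = cfg[outcome]
        return cls(
            outcome=outcome,
            intercept=float(eq["intercept"]),
            coefficients={k: float(v) for k, v in eq["coefficients"].items()},
            race_offsets={k: float(v) for k, v in eq.get("race_offsets", {}).items()},
            references={k: float(v) for k, v in cfg["references"].items()},
        )

    def linear_predictor(
        self,
        age: np.ndarray | float,
        male: np.ndarray | float,
        bmi: np.ndarray | float,
        hba1c: np.ndarray | float,
        hypertension: np.ndarray | float,
        race: np.ndarray | str,
    ) -> np.ndarray:
        c, r = self.coefficients, self.references
        lp = (
            self.intercept
            + c["age"] * (np.asarray(age, dtype=float) - r["age"])
            + c["male"] * np.asarray(male, dtype=float)
            + c["bmi"] * (np.asarray(bmi, dtype=float) - r["bmi"])
            + c["hba1c"] * (np.asarray(hba1c, dtype=float) - r["hba1c"])
            + c["hypertension"] * np.asarray(hypertension, dtype=float)
        )
        if self.race_offsets:
            race_arr = np.asarray(race, dtype=object)
            try:
                offsets = np.vectorize(self.race_offsets.__getitem__)(race_arr)
            except KeyError as exc:
                raise ConfigurationError(
                    f"risk equation {self.outcome!r} has no race offset for {exc.args[0]!r}"
                ) from None
            lp = lp + offsets.astype(float)
        return lp

    def probability_frame(self, df: pd.DataFrame) -> np.ndarray:
        """Vectorized annual probabilities for a cohort frame with columns
        age, sex, bmi, hba1c, hypertension, race_ethnicity."""
        return expit(
            self.linear_predictor(
                df["age"].to_numpy(dtype=float),
                (df["sex"].to_numpy(dtype=object) == "male").astype(float),
                df["bmi"].to_numpy(dtype=float),
                df["hba1c"].to_numpy(dtype=float),
                df["hypertension"].to_numpy(dtype=float),
                df["race_ethnicity"].to_numpy(dtype=object),
            )
        )


def annual_probability(individual: Mapping[str, Any] | pd.Series, eq: RiskEquation) -> float:
    """Annual transition probability for a single individual."""
    for col in ("age", "sex", "bmi", "hba1c", "hypertension", "race_ethnicity"):
        if col not in individual:
            raise ConfigurationError(f"individual record is missing covariate {col!r}")
    lp = eq.linear_predictor(
        float(individual["age"]),
        1.0 if individual["sex"] == "male" else 0.0,
        float(individual["bmi"]),
        float(individual["hba1c"]),
        float(bool(individual["hypertension"])),
        individual["race_ethnicity"],
    )
    return float(expit(lp))


def rr_from_delta(delta_servings: float, rr_per_serving: float, attenuation: float = 1.0):
    """Log-linear dose-response: RR = exp(attenuation * delta * ln(rr))."""
    if np.any(np.asarray(rr_per_serving) <= 0):
        raise ValueError("rr_per_serving must be positive")
    return np.exp(attenuation * np.asarray(delta_servings) * np.log(rr_per_serving))


def adjust_probability(p, rr):
    """Apply a relative risk on the rate scale: p' = 1 - (1-p)^rr.

    Exactly preserves p=0 and p=1, equals p at rr=1, and stays in [0, 1]
    for any positive rr (unlike naive multiplication).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** rr


@dataclass(frozen=True)
class DietDiseaseRR:
    """Diet-disease pathway: RR per +1 serving/day F&V for CHD and stroke
    with multiplicative log-RR attenuation by age band."""

    rr_chd_per_serving: float
    rr_stroke_per_serving: float
    age_attenuation_bands: tuple[tuple[float, float, float], ...]
    recurrent_chd_weight: float = 0.6

    def __post_init__(self) -> None:
        if self.rr_chd_per_serving <= 0 or self.rr_stroke_per_serving <= 0:
            raise ConfigurationError("relative risks must be positive")
        for lo, hi, mult in self.age_attenuation_bands:
            if not 0.0 < mult <= 1.0:
                raise ConfigurationError(f"attenuation {mult} outside (0, 1]")
            if lo >= hi:
                raise ConfigurationError(f"attenuation band ({lo}, {hi}) out of order")

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any] | None = None) -> "DietDiseaseRR":
        cfg = DIET_RR_DEFAULTS if cfg is None else cfg
        return cls(
            rr_chd_per_serving=float(cfg["rr_chd_per_serving"]),
            rr_stroke_per_serving=float(cfg["rr_stroke_per_serving"]),
            age_attenuation_bands=tuple(tuple(map(float, b)) for b in cfg["age_attenuation_bands"]),
            recurrent_chd_weight=float(cfg.get("recurrent_chd_weight", 0.6)),
        )

    def attenuation(self, age) -> np.ndarray:
        return attenuation_for_age(age, self.age_attenuation_bands)

    def rr_chd(self, delta_servings, age):
        return rr_from_delta(delta_servings, self.rr_chd_per_serving, self.attenuation(age))

    def rr_stroke(self, delta_servings, age):
        return rr_from_delta(delta_servings, self.rr_stroke_per_serving, self.attenuation(age))

    def rr_recurrent(self, delta_servings, age):
        """CHD/stroke log-RR mixture applied to the pooled recurrent-event
        probability."""
        w = self.recurrent_chd_weight
        log_rr = w * np.log(self.rr_chd_per_serving) + (1 - w) * np.log(self.rr_stroke_per_serving)
        return np.exp(self.attenuation(age) * np.asarray(delta_servings) * log_rr)


def attenuation_for_age(age, bands) -> np.ndarray:
    """Piecewise-constant attenuation multiplier by age band."""
    age = np.asarray(age, dtype=float)
    out = np.ones_like(age)
    matched = np.zeros_like(age, dtype=bool)
    for lo, hi, mult in bands:
        mask = (age >= lo) & (age < hi) & ~matched
        out[mask] = mult
        matched |= mask
    return out


@dataclass(frozen=True)
class TrajectoryRules:
    """Secular per-year drifts of the continuous risk factors (default 0)."""

    bmi_drift: float = 0.0
    hba1c_drift: float = 0.0
    fv_drift: float = 0.0


def risk_factor_state(
    baseline: pd.DataFrame,
    year_index: int,
    rules: TrajectoryRules,
    enrolled: np.ndarray | bool,
    deltas: Mapping[str, float],
) -> dict[str, np.ndarray]:
    """Risk factors at cycle ``year_index`` as a pure function of baseline.

    Age advances by ``year_index``; drifts accrue linearly; intervention
    deltas are applied as level shifts wherever ``enrolled`` holds.  The
    fruit/vegetable delta is carried on the combined daily total.
    """
    if year_index < 1:
        raise ValueError("year_index must be >= 1")
    enrolled = np.asarray(enrolled, dtype=float)
    t = float(year_index)
    fv0 = baseline["fruit_servings"].to_numpy(dtype=float) + baseline["veg_servings"].to_numpy(dtype=float)
    return {
        "age": baseline["age"].to_numpy(dtype=float) + t,
        "bmi": baseline["bmi"].to_numpy(dtype=float) + rules.bmi_drift * t + enrolled * deltas["bmi"],
        "hba1c": baseline["hba1c"].to_numpy(dtype=float) + rules.hba1c_drift * t + enrolled * deltas["hba1c"],
        "fv_total": fv0 + rules.fv_drift * t + enrolled * deltas["fv_servings"],
    }


def update_risk_factors(
    individual: Mapping[str, Any] | pd.Series,
    year_index: int,
    rules: TrajectoryRules,
    enrolled: bool,
    deltas: Mapping[str, float],
) -> dict[str, Any]:
    """Single-record view of :func:`risk_factor_state`.

    Returns a copy of the record with age, BMI, HbA1c and diet evaluated
    at ``year_index`` from its baseline values.  The F&V shift is split
    across fruit and vegetables in proportion to their baseline shares
    (evenly when both are zero) so the daily total moves by exactly the
    configured delta.
    """
    frame = pd.DataFrame([dict(individual)])
    state = risk_factor_state(frame, year_index, rules, np.array([enrolled]), deltas)
    out = dict(individual)
    out["age"] = float(state["age"][0])
    out["bmi"] = float(state["bmi"][0])
    out["hba1c"] = float(state["hba1c"][0])
    f0 = float(individual["fruit_servings"])
    v0 = float(individual["veg_servings"])
    shift = float(state["fv_total"][0]) - (f0 + v0)
    if f0 + v0 > 0:
        out["fruit_servings"] = f0 + shift * f0 / (f0 + v0)
        out["veg_servings"] = v0 + shift * v0 / (f0 + v0)
    else:
        out["fruit_servings"] = f0 + shift / 2.0
        out["veg_servings"] = v0 + shift / 2.0
    return out


@dataclass
class MortalityTable:
    """Annual non-CVD death probabilities by integer age and sex."""

    ages: np.ndarray
    q_female: np.ndarray
    q_male: np.ndarray

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any] | None = None) -> "MortalityTable":
        cfg = MORTALITY_DEFAULTS if cfg is None else cfg
        if cfg.get("table"):
            rows = pd.DataFrame(cfg["table"], columns=["age", "sex", "annual_probability"])
            return cls.from_frame(rows)
        g = cfg["gompertz"]
        ages = np.arange(int(cfg["age_min"]), int(cfg["age_max"]) + 1)
        q_male = np.minimum(g["cap"], g["male_c"] * np.exp(g["male_b"] * ages))
        q_female = np.minimum(g["cap"], g["female_ratio"] * q_male)
        return cls(ages=ages, q_female=q_female, q_male=q_male)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MortalityTable":
        df = df.sort_values("age")
        ages = np.array(sorted(df["age"].unique()), dtype=int)
        by_sex = {}
        for sex in ("female", "male"):
            sub = df[df["sex"] == sex].set_index("age")["annual_probability"]
            if not set(ages).issubset(sub.index):
                raise ConfigurationError(f"mortality table is missing ages for sex {sex!r}")
            by_sex[sex] = sub.loc[ages].to_numpy(dtype=float)
        if np.any((by_sex["female"] < 0) | (by_sex["female"] > 1)) or np.any(
            (by_sex["male"] < 0) | (by_sex["male"] > 1)
        ):
            raise ConfigurationError("mortality probabilities must lie in [0, 1]")
        return cls(ages=ages, q_female=by_sex["female"], q_male=by_sex["male"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "MortalityTable":
        return cls.from_frame(pd.read_csv(path))

    def probability(self, age, male) -> np.ndarray:
        """Annual probability, clamped to the table's age range."""
        idx = np.clip(np.round(np.asarray(age, dtype=float)).astype(int) - self.ages[0],
                      0, len(self.ages) - 1)
        male = np.asarray(male, dtype=bool)
        return np.where(male, self.q_male[idx], self.q_female[idx])
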
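"""Synthetic survey-weighted cohort generation.

Generates cohorts of US adults aged 40-79 with prevalent diabetes and food
insecurity that match the published baseline marginals of the eligible
national sample: truncated-normal continuous risk factors joined through a
Gaussian copula, independent categorical draws, an age-tilted CVD-history
probability calibrated to the published 30% prevalence, and lognormal
survey weights rescaled to the represented population total (6.5 million
by default).

Cohorts are plain :class:`pandas.DataFrame` objects with one row per
individual; :data:`COHORT_COLUMNS` fixes the column order, which is also
the on-disk CSV schema (booleans as 0/1, categories as literal labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .config import POPULATION_DEFAULTS, ConfigurationError

__all__ = [
    "ContinuousMarginal",
    "PopulationSpec",
    "default_population_spec",
    "generate_cohort",
    "weighted_summary",
    "validate_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "person_id",
    "survey_weight",
    "age",
    "sex",
    "race_ethnicity",
    "education",
    "income_poverty_ratio",
    "insurance",
    "food_insecure",
    "diabetes",
    "hypertension",
    "cvd_history",
    "angina",
    "chd",
    "mi",
    "stroke",
    "bmi",
    "hba1c",
    "fruit_servings",
    "veg_servings",
]

_BOOL_COLUMNS = [
    "food_insecure",
    "diabetes",
    "hypertension",
    "cvd_history",
    "angina",
    "chd",
    "mi",
    "stroke",
]

_CVD_SUBFLAGS = ["angina", "chd", "mi", "stroke"]


def _solve_truncnorm_params(mean: float, sd: float, lower: float, upper: float) -> tuple[float, float]:
    """Latent (loc, scale) whose truncation to [lower, upper] has exactly
    the target mean and SD (moment matching)."""

    def resid(p: np.ndarray) -> list[float]:
        loc, log_scale = p
        scale = float(np.exp(log_scale))
        a, b = (lower - loc) / scale, (upper - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.root(resid, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise ConfigurationError(
            f"cannot moment-match a truncated normal to mean={mean}, sd={sd} "
            f"on [{lower}, {upper}]"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


@dataclass(frozen=True)
class ContinuousMarginal:
    """Marginal distribution for one continuous variable.

    ``mean``/``sd`` are the target moments of the *realized* (truncated)
    distribution; the underlying parameters are moment-matched at
    construction.  Families: ``truncnorm`` (symmetric-ish risk factors)
    and ``gamma`` (skewed nonnegative quantities such as daily servings,
    whose printed CV can exceed what a lower-truncated normal attains).
    """

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf
    family: str = "truncnorm"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"negative sd {self.sd}")
        if not self.lower <= self.upper:
            raise ConfigurationError(
                f"truncation bounds out of order: ({self.lower}, {self.upper})"
            )
        if self.family not in ("truncnorm", "gamma"):
            raise ConfigurationError(f"unknown marginal family {self.family!r}")
        if self.family == "gamma" and (self.mean <= 0 or self.lower < 0):
            raise ConfigurationError("gamma marginals need mean > 0 and lower >= 0")
        if self.sd > 0 and self.family == "truncnorm":
            loc, scale = _solve_truncnorm_params(self.mean, self.sd, self.lower, self.upper)
            object.__setattr__(self, "_loc", loc)
            object.__setattr__(self, "_scale", scale)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function; degenerate (sd=0) marginals return the mean."""
        u = np.asarray(u, dtype=float)
        if self.sd == 0:
            return np.full_like(u, self.mean)
        if self.family == "gamma":
            # shape/scale from the moments; upper truncation by rescaling
            # the copula uniforms into the retained probability mass
            k = (self.mean / self.sd) ** 2
            theta = self.sd**2 / self.mean
            cap = stats.gamma.cdf(self.upper, k, scale=theta)
            return stats.gamma.ppf(u * cap, k, scale=theta)
        loc, scale = self._loc, self._scale
        a, b = (self.lower - loc) / scale, (self.upper - loc) / scale
        return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


@dataclass
class PopulationSpec:
    """Distributional recipe the cohort generator samples from.

    ``continuous`` maps variable name to :class:`ContinuousMarginal`;
    ``categorical`` maps variable name to a label->probability mapping;
    ``correlation`` is the latent-Gaussian correlation matrix over the
    continuous variables (order = ``list(continuous)``).
    """

    continuous: dict[str, ContinuousMarginal]
    categorical: dict[str, dict[str, float]]
    correlation: np.ndarray
    hypertension: float
    cvd_prevalence: float
    cvd_age_slope: float
    cvd_subflags: dict[str, float]
    insurance_raw_percent: dict[str, float] = field(default_factory=dict)
    total_population: float = 6_500_000.0
    weight_sigma: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        self.correlation = np.asarray(self.correlation, dtype=float)
        k = len(self.continuous)
        if self.correlation.shape != (k, k):
            raise ConfigurationError(
                f"correlation matrix shape {self.correlation.shape} does not match "
                f"{k} continuous variables"
            )
        if not np.allclose(self.correlation, self.correlation.T, atol=1e-12):
            raise ConfigurationError("correlation matrix is not symmetric")
        for name, probs in self.categorical.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"category probabilities for {name!r} sum to {total}, not 1"
                )

    @property
    def continuous_names(self) -> list[str]:
        return list(self.continuous)


def _insurance_probs(raw_percent: Mapping[str, float]) -> dict[str, float]:
    total = sum(raw_percent.values())
    return {k: v / total for k, v in raw_percent.items()}


def default_population_spec(population_cfg: Mapping[str, Any] | None = None) -> PopulationSpec:
    """Population preset matching the published baseline-characteristics table.

    Insurance percentages are renormalized to a proper distribution (the
    published categories overlap and sum to 112.2%); the raw values are
    retained on the spec for reference.
    """
    cfg = dict(POPULATION_DEFAULTS if population_cfg is None else population_cfg)
    continuous = {
        name: ContinuousMarginal(
            m["mean"], m["sd"], m.get("lower", -np.inf), m.get("upper", np.inf),
            m.get("family", "truncnorm"),
        )
        for name, m in cfg["continuous"].items()
    }
    names = list(continuous)
    corr = np.eye(len(names))
    for a, b, rho in cfg.get("correlations", []):
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = float(rho)

    categorical = {name: dict(probs) for name, probs in cfg["categorical"].items()}
    categorical["insurance"] = _insurance_probs(cfg["insurance_raw_percent"])

    cvd = cfg["cvd"]
    return PopulationSpec(
        continuous=continuous,
        categorical=categorical,
        correlation=corr,
        hypertension=float(cfg["hypertension"]),
        cvd_prevalence=float(cvd["prevalence"]),
        cvd_age_slope=float(cvd["age_log_odds_slope"]),
        cvd_subflags=dict(cvd["subflags"]),
        insurance_raw_percent=dict(cfg["insurance_raw_percent"]),
        total_population=float(cfg["total_population"]),
        weight_sigma=float(cfg["weight_sigma"]),
    )


def _calibrate_cvd_intercept(spec: PopulationSpec) -> float:
    """Solve for the logistic intercept so that the age-tilted CVD-history
    probability integrates to the target marginal prevalence over the age
    marginal."""
    age = spec.continuous["age"]
    slope = spec.cvd_age_slope
    target = spec.cvd_prevalence
    if slope == 0 or age.sd == 0:
        centre = 0.0 if age.sd == 0 else 0.0
        return float(np.log(target / (1 - target)) - slope * centre)
    a = (age.lower - age.mean) / age.sd
    b = (age.upper - age.mean) / age.sd
    # Gauss-Legendre integration over the truncated age support
    nodes, weights = np.polynomial.legendre.leggauss(200)
    lo = age.mean + a * age.sd
    hi = age.mean + b * age.sd
    x = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    pdf = stats.truncnorm.pdf(x, a, b, loc=age.mean, scale=age.sd)
    w = 0.5 * (hi - lo) * weights * pdf

    def marginal(alpha: float) -> float:
        return float(np.sum(w * expit(alpha + slope * (x - age.mean))) - target)

    return float(optimize.brentq(marginal, -30.0, 30.0, xtol=1e-12))


def _sample_categorical(
    rng: np.random.Generator, probs: Mapping[str, float], n: int
) -> np.ndarray:
    labels = np.array(list(probs), dtype=object)
    p = np.array([probs[str(l)] for l in labels], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(labels), size=n, p=p)
    return labels[idx]


def generate_cohort(spec: PopulationSpec, n: int, seed: int | None = None) -> pd.DataFrame:
    """Sample ``n`` individuals from a :class:`PopulationSpec`.

    Continuous variables are drawn through a latent Gaussian copula so the
    marginals stay exactly truncated-normal while respecting the latent
    correlation matrix.  Identical ``(spec, n, seed)`` triples yield
    identical cohorts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    eigvals = np.linalg.eigvalsh(spec.correlation)
    if eigvals.min() < -1e-10:
        raise ConfigurationError(
            f"continuous correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x706F70]))

    # latent Gaussian -> uniform -> truncated-normal marginals
    k = len(spec.continuous)
    corr = spec.correlation + 1e-12 * np.eye(k)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, k)) @ chol.T
    u = stats.norm.cdf(z)
    data: dict[str, Any] = {}
    for j, (name, marginal) in enumerate(spec.continuous.items()):
        data[name] = marginal.ppf(u[:, j])

    for name, probs in spec.categorical.items():
        data[name] = _sample_categorical(rng, probs, n)

    data["hypertension"] = rng.random(n) < spec.hypertension

    # CVD history with an age-increasing logistic probability whose
    # intercept is calibrated to the marginal prevalence
    alpha = _calibrate_cvd_intercept(spec)
    age_mean = spec.continuous["age"].mean
    p_cvd = expit(alpha + spec.cvd_age_slope * (data["age"] - age_mean))
    cvd = rng.random(n) < p_cvd
    data["cvd_history"] = cvd

    # sub-conditions conditional on any CVD history; at least one flag is
    # forced (the highest-prevalence one) so history <=> any flag holds
    prev = spec.cvd_prevalence
    any_flag = np.zeros(n, dtype=bool)
    for flag, marg in spec.cvd_subflags.items():
        q = min(marg / prev, 1.0) if prev > 0 else 0.0
        data[flag] = cvd & (rng.random(n) < q)
        any_flag |= data[flag]
    fallback = max(spec.cvd_subflags, key=spec.cvd_subflags.get)
    data[fallback] = data[fallback] | (cvd & ~any_flag)

    # survey weights: lognormal, rescaled to the represented total
    if spec.weight_sigma > 0:
        w = rng.lognormal(mean=0.0, sigma=spec.weight_sigma, size=n)
    else:
        w = np.ones(n)
    data["survey_weight"] = w * (spec.total_population / w.sum())

    data["person_id"] = np.array([f"p{i:07d}" for i in range(n)], dtype=object)
    data["food_insecure"] = np.ones(n, dtype=bool)
    data["diabetes"] = np.ones(n, dtype=bool)

    cohort = pd.DataFrame(data)[COHORT_COLUMNS]
    validate_cohort(cohort)
    return cohort


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Raise ``ValueError`` if any baseline-record invariant is violated."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    if (cohort["survey_weight"] <= 0).any():
        raise ValueError("survey weights must be positive")
    if ((cohort["age"] < 40) | (cohort["age"] > 79)).any():
        raise ValueError("baseline ages must lie in [40, 79]")
    if (cohort["bmi"] <= 10).any():
        raise ValueError("BMI must exceed 10 kg/m^2")
    if ((cohort["hba1c"] < 4) | (cohort["hba1c"] > 18)).any():
        raise ValueError("HbA1c must lie in [4, 18] %")
    if (cohort[["fruit_servings", "veg_servings"]] < 0).any().any():
        raise ValueError("diet servings must be nonnegative")
    for col in ("diabetes", "food_insecure"):
        if not cohort[col].astype(bool).all():
            raise ValueError(f"every baseline record must have {col} = True")
    any_flag = cohort[_CVD_SUBFLAGS].astype(bool).any(axis=1)
    if not (cohort["cvd_history"].astype(bool) == any_flag).all():
        raise ValueError("cvd_history must hold iff at least one sub-flag holds")


def weighted_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Survey-weighted means/SDs and category percentages, one row per
    statistic (columns: variable, category, statistic, value)."""
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    w = cohort["survey_weight"].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("survey weights must be positive")
    wsum = w.sum()
    rows: list[tuple[str, str, str, float]] = []

    for var in ("age", "bmi", "hba1c", "fruit_servings", "veg_servings"):
        x = cohort[var].to_numpy(dtype=float)
        mean = float(np.sum(w * x) / wsum)
        var_w = float(np.sum(w * (x - mean) ** 2) / wsum)
        rows.append((var, "", "weighted_mean", mean))
        rows.append((var, "", "weighted_sd", float(np.sqrt(var_w))))

    for var in ("sex", "race_ethnicity", "education", "income_poverty_ratio", "insurance"):
        values = cohort[var].astype(str)
        for label in sorted(values.unique()):
            pct = float(100.0 * w[(values == label).to_numpy()].sum() / wsum)
            rows.append((var, label, "weighted_percent", pct))

    for var in ("hypertension", "cvd_history", *_CVD_SUBFLAGS, "diabetes", "food_insecure"):
        mask = cohort[var].astype(bool).to_numpy()
        rows.append((var, "", "weighted_percent", float(100.0 * w[mask].sum() / wsum)))

    return pd.DataFrame(rows, columns=["variable", "category", "statistic", "value"])


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort with booleans encoded as 0/1."""
    out = cohort.copy()
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path)
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(int).astype(bool)
    df = df[COHORT_COLUMNS]
    validate_cohort(df)
    return df
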
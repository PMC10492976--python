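"""Random-effects pooling of study-level intervention effects.

The produce prescription literature reports per-study changes in fruit and
vegetable intake (servings/day), BMI (kg/m^2) and HbA1c (percentage
points).  This module pools such study sets with DerSimonian-Laird
random-effects meta-analysis and exposes the pooled base-case effects,
with normal uncertainty distributions recovered from 95% CIs, for the
probabilistic sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import EFFECTS_DEFAULTS

__all__ = [
    "StudyEffect",
    "EffectEstimate",
    "InterventionEffects",
    "pool_random_effects",
    "effect_sampler",
    "effect_percentile",
    "synthetic_study_set",
    "read_study_csv",
    "forest_table",
]

OUTCOMES = ("fv_servings", "bmi", "hba1c")

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class StudyEffect:
    """One study's effect estimate for a single outcome."""

    study_id: str
    outcome: str
    estimate: float
    standard_error: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.standard_error <= 0:
            raise ValueError(f"standard_error must be positive, got {self.standard_error}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; expected one of {OUTCOMES}")


@dataclass(frozen=True)
class PooledEffect:
    mean: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    k: int


def pool_random_effects(studies: Sequence[StudyEffect]) -> PooledEffect:
    """DerSimonian-Laird random-effects pooling of one outcome's studies.

    Between-study variance tau^2 = max(0, (Q - (k-1)) / (S1 - S2/S1)) with
    fixed-effect weights w_i = 1/se_i^2; the pooled mean uses weights
    1/(se_i^2 + tau^2) and CI = mean +/- 1.96 * pooled SE.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("cannot pool an empty study set")
    outcomes = {s.outcome for s in studies}
    if len(outcomes) > 1:
        raise ValueError(f"cannot pool mixed outcomes: {sorted(outcomes)}")
    y = np.array([s.estimate for s in studies], dtype=float)
    se = np.array([s.standard_error for s in studies], dtype=float)
    k = len(y)

    w = 1.0 / se**2
    mu_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu_fe) ** 2))
    if k > 1:
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0

    w_re = 1.0 / (se**2 + tau2)
    mean = float(np.sum(w_re * y) / np.sum(w_re))
    pooled_se = float(np.sqrt(1.0 / np.sum(w_re)))
    return PooledEffect(
        mean=mean,
        se=pooled_se,
        ci_low=mean - _Z95 * pooled_se,
        ci_high=mean + _Z95 * pooled_se,
        tau2=tau2,
        k=k,
    )


@dataclass(frozen=True)
class EffectEstimate:
    """Pooled mean with a 95% CI; the PSA treats it as normal with
    SD = (ci_high - ci_low) / (2 * 1.96)."""

    mean: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValueError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket mean {self.mean}"
            )

    @property
    def sd(self) -> float:
        return (self.ci_high - self.ci_low) / (2.0 * _Z95)

    def percentile(self, p: float) -> float:
        if not 0.0 < p < 1.0:
            raise ValueError(f"percentile must lie in (0, 1), got {p}")
        if self.sd == 0:
            return self.mean
        return float(stats.norm.ppf(p, loc=self.mean, scale=self.sd))

    @classmethod
    def from_pooled(cls, pooled: PooledEffect) -> "EffectEstimate":
        return cls(pooled.mean, pooled.ci_low, pooled.ci_high)


@dataclass
class InterventionEffects:
    """Base-case intervention effect triple plus enrollment rules.

    Deltas are level shifts sustained while enrolled; on disenrollment all
    benefits cease (the conservative no-persistence assumption).
    """

    fv_servings: EffectEstimate
    bmi: EffectEstimate
    hba1c: EffectEstimate
    participation_fraction: float = 1.0
    persistence: str = "benefits_cease_on_exit"

    def __post_init__(self) -> None:
        if not 0.0 <= self.participation_fraction <= 1.0:
            raise ValueError("participation_fraction must lie in [0, 1]")

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any] | None = None) -> "InterventionEffects":
        cfg = EFFECTS_DEFAULTS if cfg is None else cfg
        return cls(
            fv_servings=EffectEstimate(**{k: cfg["fv_servings"][k] for k in ("mean", "ci_low", "ci_high")}),
            bmi=EffectEstimate(**{k: cfg["bmi"][k] for k in ("mean", "ci_low", "ci_high")}),
            hba1c=EffectEstimate(**{k: cfg["hba1c"][k] for k in ("mean", "ci_low", "ci_high")}),
            participation_fraction=float(cfg.get("participation_fraction", 1.0)),
            persistence=str(cfg.get("persistence", "benefits_cease_on_exit")),
        )

    def estimate(self, outcome: str) -> EffectEstimate:
        if outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {outcome!r}")
        return getattr(self, outcome)

    def deltas(self) -> dict[str, float]:
        """Base-case (mean) deltas."""
        return {o: self.estimate(o).mean for o in OUTCOMES}

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        """One PSA draw of the effect triple (independent normals)."""
        return {
            o: float(rng.normal(self.estimate(o).mean, self.estimate(o).sd))
            for o in OUTCOMES
        }

    def at_percentile(self, p: float) -> dict[str, float]:
        """All three deltas moved jointly to percentile ``p`` of their
        distributions, oriented so higher ``p`` means larger benefit
        (larger F&V gain, larger BMI/HbA1c reduction)."""
        out = {}
        for o in OUTCOMES:
            est = self.estimate(o)
            # protective deltas are negative for bmi/hba1c: mirror p so the
            # sweep moves all outcomes toward benefit together
            q = p if est.mean >= 0 else 1.0 - p
            out[o] = est.percentile(q)
        return out


def effect_sampler(
    effects: InterventionEffects, seed: int
) -> Iterator[dict[str, float]]:
    """Infinite reproducible stream of PSA effect-triple draws."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xEFF]))
    while True:
        yield effects.sample(rng)


def effect_percentile(effects: InterventionEffects, outcome: str, p: float) -> float:
    """Effect value at percentile ``p`` of the outcome's normal distribution."""
    return effects.estimate(outcome).percentile(p)


def synthetic_study_set(
    outcome: str,
    k: int = 8,
    seed: int = 0,
    true_mean: float | None = None,
    tau: float = 0.15,
) -> list[StudyEffect]:
    """Generate a synthetic study set for fixtures and demonstrations.

    Draws study-level true effects around the base-case pooled mean with
    between-study SD ``tau`` and heterogeneous standard errors.  This is a
    synthetic stand-in for the (unpublished) study-level table.
    """
    if true_mean is None:
        true_mean = InterventionEffects.from_config().estimate(outcome).mean
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x57D]))
    studies = []
    for i in range(k):
        se = float(rng.uniform(0.08, 0.35))
        theta = float(rng.normal(true_mean, tau))
        est = float(rng.normal(theta, se))
        n = int(rng.integers(40, 400))
        studies.append(StudyEffect(f"study_{i + 1:02d}", outcome, est, se, n))
    return studies


def read_study_csv(path: str | Path) -> list[StudyEffect]:
    """Read a study table (study_id, outcome, estimate, standard_error, n)."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        n = getattr(row, "n", None)
        n = None if n is None or (isinstance(n, float) and math.isnan(n)) else int(n)
        out.append(
            StudyEffect(str(row.study_id), str(row.outcome), float(row.estimate),
                        float(row.standard_error), n)
        )
    return out


def forest_table(studies: Sequence[StudyEffect]) -> str:
    """Plain-text forest table: per-study estimates and the pooled row."""
    pooled = pool_random_effects(studies)
    lines = [f"{'study':<12} {'estimate':>9} {'95% CI':>20}"]
    for s in studies:
        lo, hi = s.estimate - _Z95 * s.standard_error, s.estimate + _Z95 * s.standard_error
        lines.append(f"{s.study_id:<12} {s.estimate:>9.3f} ({lo:>8.3f}, {hi:>8.3f})")
    lines.append("-" * 44)
    lines.append(
        f"{'RE pooled':<12} {pooled.mean:>9.3f} ({pooled.ci_low:>8.3f}, {pooled.ci_high:>8.3f})"
        f"  tau2={pooled.tau2:.4f}"
    )
    return "\n".join(lines)
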
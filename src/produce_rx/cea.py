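"""Cost-effectiveness analysis on top of the paired microsimulation.

Implements ICERs with dominance labels, probabilistic sensitivity
analysis (every uncertain input re-drawn per Monte Carlo iteration, the
paired simulation re-run, and uncertainty intervals combined with
Rubin's rule), cost-effectiveness acceptability curves, the one-way
effect-size percentile sweep, and the break-even monthly program cost
threshold analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import default_config
from .econ_qaly import discount_factors
from .engine import (
    PairedResult,
    SimulationParams,
    aggregate,
    incremental_person_totals,
    run_paired,
)
from .meta_effects import OUTCOMES, InterventionEffects
from .risk_engine import DietDiseaseRR

__all__ = [
    "icer",
    "run_psa",
    "PSAResult",
    "rubins_combine",
    "ceac",
    "one_way_sweep",
    "threshold_monthly_cost",
    "table2_frame",
]

_Z95 = 1.959963984540054

COST_SAVING = "cost-saving"
DOMINATED = "dominated"
UNDEFINED = "undefined"

# aggregate keys carried through the PSA with Rubin-combined intervals
PSA_QUANTITIES = (
    "first_events_averted",
    "recurrent_events_averted",
    "total_events_averted",
    "qalys_gained",
    "intervention_food_cost",
    "intervention_admin_cost",
    "intervention_cost_total",
    "healthcare_savings",
    "productivity_savings",
    "net_cost_healthcare",
    "net_cost_societal",
)


def icer(net_cost: float, qalys_gained: float) -> float | str:
    """Incremental cost-effectiveness ratio or a dominance label.

    Returns the $/QALY ratio when QALYs are gained at positive net cost;
    ``cost-saving`` when QALYs are gained and money is saved; ``dominated``
    when QALYs are lost at positive net cost; ``undefined`` otherwise.
    """
    if qalys_gained > 0:
        if net_cost < 0:
            return COST_SAVING
        return float(net_cost / qalys_gained)
    if qalys_gained < 0 and net_cost > 0:
        return DOMINATED
    return UNDEFINED


def rubins_combine(
    point_estimates: Sequence[float], within_variances: Sequence[float]
) -> tuple[float, float, tuple[float, float]]:
    """Combine per-draw estimates and their within-draw sampling variances.

    Total variance = mean within-draw variance + (1 + 1/m) * between-draw
    variance; the 95% UI is mean +/- 1.96 * sqrt(total).
    """
    points = np.asarray(point_estimates, dtype=float)
    within = np.asarray(within_variances, dtype=float)
    m = len(points)
    if m < 2:
        raise ValueError("Rubin's rule needs at least 2 draws")
    if len(within) != m:
        raise ValueError("point estimates and within-draw variances differ in length")
    mean = float(points.mean())
    w_bar = float(within.mean())
    between = float(points.var(ddof=1))
    total = w_bar + (1.0 + 1.0 / m) * between
    half = _Z95 * math.sqrt(total)
    return mean, total, (mean - half, mean + half)


def ceac(
    delta_costs: Sequence[float],
    delta_qalys: Sequence[float],
    wtp_grid: Sequence[float],
) -> pd.DataFrame:
    """Probability cost-effective per willingness-to-pay value.

    A draw counts as cost effective at WTP lambda when its net monetary
    benefit lambda * dQALY - dCost is positive.
    """
    dc = np.asarray(delta_costs, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    if len(dc) == 0 or len(dc) != len(dq):
        raise ValueError("need equal-length nonempty draw vectors")
    rows = [
        {"wtp": float(w), "p_cost_effective": float(np.mean(w * dq - dc > 0))}
        for w in wtp_grid
    ]
    return pd.DataFrame(rows)


def _weighted_total_variance(values: np.ndarray, weights: np.ndarray) -> float:
    """With-replacement sampling variance of the weighted population total
    sum(w_i * x_i), treating the cohort as an i.i.d. weighted sample."""
    z = weights * values
    n = len(z)
    if n < 2:
        return 0.0
    return float(n / (n - 1) * np.sum((z - z.mean()) ** 2))


def _draw_params(
    base_cfg: Mapping[str, Any], rng: np.random.Generator
) -> SimulationParams:
    """Sample one PSA parameter set: intervention effects, diet-disease
    log-RRs, program and event costs, and utility inputs, each from its
    configured uncertainty distribution."""
    effects = InterventionEffects.from_config(base_cfg["effects"])
    deltas = effects.sample(rng)

    params = SimulationParams.from_config(base_cfg, deltas=deltas)

    rr_cfg = base_cfg["diet_rr"]
    se = rr_cfg["log_rr_se"]
    diet = replace(
        params.diet_rr,
        rr_chd_per_serving=float(
            np.exp(rng.normal(np.log(rr_cfg["rr_chd_per_serving"]), se["chd"]))
        ),
        rr_stroke_per_serving=float(
            np.exp(rng.normal(np.log(rr_cfg["rr_stroke_per_serving"]), se["stroke"]))
        ),
    )

    c = params.costs
    rel = float(base_cfg["costs"].get("psa_relative_se", 0.10))
    draw_pos = lambda mean: float(max(0.0, rng.normal(mean, rel * mean))) if mean > 0 else 0.0
    costs = replace(
        c,
        monthly_redeemed=draw_pos(c.monthly_redeemed),
        acute_cost_chd=draw_pos(c.acute_cost_chd),
        acute_cost_stroke=draw_pos(c.acute_cost_stroke),
        productivity_chd=draw_pos(c.productivity_chd),
        productivity_stroke=draw_pos(c.productivity_stroke),
        hba1c_cost_slope=draw_pos(c.hba1c_cost_slope),
    )

    u = params.utilities
    u_cfg = base_cfg["utilities"]
    dec_rel = float(u_cfg.get("psa_decrement_relative_se", 0.10))
    reg = dict(u.eq5d_regression)
    reg["intercept"] = float(
        rng.normal(reg["intercept"], float(u_cfg.get("psa_intercept_se", 0.01)))
    )
    utilities = replace(
        u,
        decrement_chd=float(max(0.0, rng.normal(u.decrement_chd, dec_rel * u.decrement_chd))),
        decrement_stroke=float(max(0.0, rng.normal(u.decrement_stroke, dec_rel * u.decrement_stroke))),
        eq5d_regression=reg,
    )

    return replace(params, diet_rr=diet, costs=costs, utilities=utilities)


@dataclass
class PSAResult:
    """Per-draw incremental outcomes and Rubin-combined summaries."""

    draws: pd.DataFrame  # one row per (draw_id, horizon)
    n_draws: int
    base_seed: int
    horizons: tuple[str, ...]

    def _horizon_frame(self, horizon: str) -> pd.DataFrame:
        sub = self.draws[self.draws["horizon"] == horizon]
        if sub.empty:
            raise ValueError(f"no PSA draws recorded for horizon {horizon!r}")
        return sub

    def summary(self, horizon: str = "lifetime") -> pd.DataFrame:
        """Rubin-combined mean and 95% UI per quantity at a horizon."""
        sub = self._horizon_frame(horizon)
        rows = []
        for q in PSA_QUANTITIES:
            within = sub[f"within_var_{q}"] if f"within_var_{q}" in sub else np.zeros(len(sub))
            mean, total, (lo, hi) = rubins_combine(sub[q].to_numpy(), np.asarray(within))
            rows.append(
                {"quantity": q, "mean": mean, "total_variance": total,
                 "ui95_low": lo, "ui95_high": hi}
            )
        return pd.DataFrame(rows)

    def icers(self, horizon: str = "lifetime") -> dict[str, float | str]:
        """Ratio-of-means ICERs (mean net cost / mean QALYs gained)."""
        sub = self._horizon_frame(horizon)
        dq = float(sub["qalys_gained"].mean())
        return {
            "healthcare": icer(float(sub["net_cost_healthcare"].mean()), dq),
            "societal": icer(float(sub["net_cost_societal"].mean()), dq),
        }

    def ceac(
        self, wtp_grid: Sequence[float], horizon: str = "lifetime",
        perspective: str = "healthcare",
    ) -> pd.DataFrame:
        sub = self._horizon_frame(horizon)
        col = {"healthcare": "net_cost_healthcare", "societal": "net_cost_societal"}[perspective]
        return ceac(sub[col].to_numpy(), sub["qalys_gained"].to_numpy(), wtp_grid)

    def scatter(self, horizon: str = "lifetime", perspective: str = "healthcare") -> pd.DataFrame:
        """Per-draw (delta cost, delta QALY) pairs for the CEA plane."""
        sub = self._horizon_frame(horizon)
        col = {"healthcare": "net_cost_healthcare", "societal": "net_cost_societal"}[perspective]
        return sub[["draw_id", "qalys_gained", col]].rename(columns={col: "net_cost"}).reset_index(drop=True)


def run_psa(
    cohort: pd.DataFrame,
    config: Mapping[str, Any] | None = None,
    n_draws: int = 1000,
    base_seed: int = 0,
    horizons: Sequence[str] = ("5y", "10y", "lifetime"),
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Each draw samples every uncertain parameter, re-runs the paired
    simulation with a draw-specific random stream, and records the
    weighted incremental outcomes together with their within-draw
    (cohort-sampling) variances for Rubin's-rule combination.
    """
    if n_draws < 2:
        raise ValueError("PSA needs at least 2 draws")
    cfg = default_config() if config is None else config
    rate = float(cfg["costs"]["discount_rate"])
    rows = []
    # one simulation stream shared by all draws: between-draw spread then
    # reflects parameter uncertainty alone, while cohort-sampling
    # uncertainty enters through the within-draw variances (the two
    # components Rubin's rule combines)
    sim_seed = int(np.random.SeedSequence([int(base_seed), 0x512]).generate_state(1)[0] % (2**31))
    for d in range(n_draws):
        rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), d, 0x95A]))
        params = _draw_params(cfg, rng)
        result = run_paired(cohort, params, seed=sim_seed)
        for horizon in horizons:
            agg = aggregate(result, horizon, discount_rate=rate)
            inc, w = incremental_person_totals(result, horizon, rate)
            row: dict[str, Any] = {"draw_id": d, "horizon": horizon}
            row.update({q: agg[q] for q in PSA_QUANTITIES})
            row["within_var_qalys_gained"] = _weighted_total_variance(inc["qalys"], w)
            row["within_var_total_events_averted"] = _weighted_total_variance(-inc["total_events"], w)
            row["within_var_first_events_averted"] = _weighted_total_variance(-inc["first_events"], w)
            row["within_var_recurrent_events_averted"] = _weighted_total_variance(-inc["recurrent_events"], w)
            hc_net = (
                inc["cost_intervention_food"] + inc["cost_intervention_admin"]
                + inc["cost_healthcare"] + inc["cost_acute_event"]
            )
            row["within_var_net_cost_healthcare"] = _weighted_total_variance(hc_net, w)
            row["within_var_net_cost_societal"] = _weighted_total_variance(
                hc_net + inc["cost_productivity"], w
            )
            row["within_var_healthcare_savings"] = _weighted_total_variance(
                -(inc["cost_healthcare"] + inc["cost_acute_event"]), w
            )
            row["within_var_productivity_savings"] = _weighted_total_variance(
                -inc["cost_productivity"], w
            )
            row["within_var_intervention_cost_total"] = _weighted_total_variance(
                inc["cost_intervention_food"] + inc["cost_intervention_admin"], w
            )
            row["within_var_intervention_food_cost"] = _weighted_total_variance(
                inc["cost_intervention_food"], w
            )
            row["within_var_intervention_admin_cost"] = _weighted_total_variance(
                inc["cost_intervention_admin"], w
            )
            rows.append(row)
    return PSAResult(
        draws=pd.DataFrame(rows), n_draws=n_draws, base_seed=int(base_seed),
        horizons=tuple(horizons),
    )


def one_way_sweep(
    cohort: pd.DataFrame,
    config: Mapping[str, Any] | None = None,
    percentiles: Sequence[float] = (0.025, 0.10, 0.25, 0.50, 0.75, 0.90, 0.975),
    seed: int = 0,
    horizon: str = "lifetime",
) -> pd.DataFrame:
    """Deterministic effect-size sweep: all three intervention deltas moved
    jointly to each percentile of their distributions (oriented toward
    benefit), the paired simulation re-run with a common stream, and the
    ICER reported per perspective."""
    for p in percentiles:
        if not 0.0 < p < 1.0:
            raise ValueError(f"percentile {p} outside (0, 1)")
    cfg = default_config() if config is None else config
    effects = InterventionEffects.from_config(cfg["effects"])
    rate = float(cfg["costs"]["discount_rate"])
    rows = []
    for p in percentiles:
        deltas = effects.at_percentile(p)
        params = SimulationParams.from_config(cfg, deltas=deltas)
        agg = aggregate(run_paired(cohort, params, seed=seed), horizon, rate)
        rows.append(
            {
                "percentile": p,
                **{f"delta_{o}": deltas[o] for o in OUTCOMES},
                "qalys_gained": agg["qalys_gained"],
                "net_cost_healthcare": agg["net_cost_healthcare"],
                "net_cost_societal": agg["net_cost_societal"],
                "icer_healthcare": icer(agg["net_cost_healthcare"], agg["qalys_gained"]),
                "icer_societal": icer(agg["net_cost_societal"], agg["qalys_gained"]),
            }
        )
    return pd.DataFrame(rows)


def discounted_enrolled_person_years(
    result: PairedResult, horizon, discount_rate: float = 0.03
) -> float:
    """Survey-weighted present value of policy-arm enrolled person-years."""
    from .engine import _resolve_horizon

    h = _resolve_horizon(result, horizon)
    disc = discount_factors(h, discount_rate)
    w = result.cohort["survey_weight"].to_numpy(dtype=float)
    return float(np.sum(w * (result.policy.enrolled[:, :h] @ disc)))


def threshold_monthly_cost(
    result: PairedResult,
    horizon: str = "lifetime",
    wtp: float = 150000.0,
    discount_rate: float = 0.03,
    perspective: str = "healthcare",
    tolerance: float = 0.10,
    max_multiple: float = 10.0,
) -> float:
    """Break-even total monthly program cost (food redemption + admin).

    Program costs enter linearly and do not feed back into health states,
    so the ICER is monotone in the monthly cost; bisection finds the cost
    at which the ICER crosses the willingness-to-pay threshold, to the
    given $/month tolerance.  Returns ``math.inf`` when no crossing
    exists below ``max_multiple`` times the current monthly cost.
    """
    agg = aggregate(result, horizon, discount_rate)
    dq = agg["qalys_gained"]
    if dq <= 0:
        raise ValueError("threshold analysis requires positive QALYs gained")
    savings = agg["healthcare_savings"]
    if perspective == "societal":
        savings += agg["productivity_savings"]
    pv_years = discounted_enrolled_person_years(result, horizon, discount_rate)
    if pv_years <= 0:
        raise ValueError("no enrolled person-years in the policy arm")

    base_total = agg["intervention_cost_total"]
    base_monthly = base_total / (12.0 * pv_years)

    def icer_at(monthly: float) -> float:
        return (12.0 * monthly * pv_years - savings) / dq

    lo, hi = 0.0, max(max_multiple * base_monthly, 1.0)
    if icer_at(hi) < wtp:
        return math.inf
    if icer_at(lo) >= wtp:
        return 0.0
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if icer_at(mid) < wtp:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_TABLE2_ROWS = [
    ("Total CVD events averted", "total_events_averted"),
    ("First CVD cases averted", "first_events_averted"),
    ("Recurrent CVD events averted", "recurrent_events_averted"),
    ("QALYs gained", "qalys_gained"),
    ("Health care cost savings, $", "healthcare_savings"),
    ("Productivity cost savings, $", "productivity_savings"),
    ("Intervention food costs, $", "intervention_food_cost"),
    ("Intervention administrative costs, $", "intervention_admin_cost"),
    ("Net change in costs, health care perspective, $", "net_cost_healthcare"),
    ("Net change in costs, societal perspective, $", "net_cost_societal"),
]


def table2_frame(psa: PSAResult) -> pd.DataFrame:
    """Headline results table: outcome rows by horizon columns, each cell
    the PSA mean with its Rubin 95% UI, plus ratio-of-means ICER rows."""
    columns: dict[str, dict[str, str]] = {}
    for horizon in psa.horizons:
        summary = psa.summary(horizon).set_index("quantity")
        cells = {}
        for label, key in _TABLE2_ROWS:
            row = summary.loc[key]
            cells[label] = f"{row['mean']:.4g} ({row['ui95_low']:.4g} to {row['ui95_high']:.4g})"
        icers = psa.icers(horizon)
        for persp in ("healthcare", "societal"):
            val = icers[persp]
            cells[f"ICER, {persp} perspective ($/QALY)"] = (
                val if isinstance(val, str) else f"{val:.0f}"
            )
        columns[horizon] = cells
    return pd.DataFrame(columns)
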
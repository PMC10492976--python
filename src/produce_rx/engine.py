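"""Paired-arm annual-cycle microsimulation.

Each individual is advanced through annual cycles until death or the
cycle cap (60 years), once under the status quo and once under the
produce prescription policy.  Both arms consume identical per-cycle
random numbers (common random numbers), so with null effects the arms
coincide person-year by person-year and every incremental quantity is
exactly zero — incremental differences reflect the intervention alone.

Within a cycle the ordering is: risk-factor update, first-event draw
(CHD vs stroke type from the relative contribution of the two first-event
equations), recurrent-event draw for those with prior CVD history, CVD
death, then non-CVD death, then accrual.  Decedents accrue only acute
event costs in their final year; annual healthcare, productivity and
utility accrue to cycle survivors; program costs accrue to enrollees
alive at cycle start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import default_config
from .econ_qaly import (
    CostParams,
    UtilityParams,
    _covariate_arrays,
    _linear_regression,
    discount_factors,
    intervention_cost,
)
from .meta_effects import InterventionEffects
from .risk_engine import (
    DietDiseaseRR,
    MortalityTable,
    RiskEquation,
    TrajectoryRules,
    adjust_probability,
    risk_factor_state,
)

__all__ = [
    "SimulationParams",
    "ArmLedger",
    "PairedResult",
    "run_paired",
    "aggregate",
    "subgroup_aggregate",
    "incremental_person_totals",
    "ledger_long_frame",
]

ARMS = ("control", "policy")

COST_CATEGORIES = ("intervention_food", "intervention_admin", "healthcare", "acute_event", "productivity")

# substream purposes for the common-random-number draws
_PURPOSES = {"first_event": 1, "first_type": 2, "recurrent": 3, "cvd_death": 4,
             "other_death": 5, "participation": 6}


@dataclass
class SimulationParams:
    """Complete parameter bundle for one paired simulation run."""

    deltas: dict[str, float]
    diet_rr: DietDiseaseRR
    equations: dict[str, RiskEquation]
    mortality: MortalityTable
    costs: CostParams
    utilities: UtilityParams
    rules: TrajectoryRules = field(default_factory=TrajectoryRules)
    participation_fraction: float = 1.0
    max_cycles: int = 60

    @classmethod
    def from_config(
        cls,
        cfg: Mapping[str, Any] | None = None,
        deltas: Mapping[str, float] | None = None,
    ) -> "SimulationParams":
        cfg = default_config() if cfg is None else cfg
        effects = InterventionEffects.from_config(cfg["effects"])
        return cls(
            deltas=dict(effects.deltas() if deltas is None else deltas),
            diet_rr=DietDiseaseRR.from_config(cfg["diet_rr"]),
            equations={
                name: RiskEquation.from_config(name, cfg["risk_equations"])
                for name in ("first_chd", "first_stroke", "recurrent_cvd", "cvd_death")
            },
            mortality=MortalityTable.from_config(cfg["mortality_table"]),
            costs=CostParams.from_config(cfg["costs"]),
            utilities=UtilityParams.from_config(cfg["utilities"]),
            participation_fraction=float(
                cfg["effects"].get("participation_fraction",
                                   cfg["scenario"].get("participation_fraction", 1.0))
            ),
            max_cycles=int(cfg["scenario"]["max_cycles"]),
        )

    def scaled_effects(self, scale: float) -> "SimulationParams":
        """Copy with all three intervention deltas multiplied by ``scale``."""
        return replace(self, deltas={k: scale * v for k, v in self.deltas.items()})


@dataclass
class ArmLedger:
    """Per-person-per-cycle record arrays for one arm, shape (n, T)."""

    alive_start: np.ndarray
    alive_end: np.ndarray
    enrolled: np.ndarray
    first_chd: np.ndarray
    first_stroke: np.ndarray
    recurrent: np.ndarray
    cvd_death: np.ndarray
    other_death: np.ndarray
    costs: dict[str, np.ndarray]
    utility: np.ndarray

    @property
    def first_event(self) -> np.ndarray:
        return self.first_chd | self.first_stroke


@dataclass
class PairedResult:
    cohort: pd.DataFrame
    control: ArmLedger
    policy: ArmLedger
    max_cycles: int
    seed: int
    participants: np.ndarray

    def arm(self, name: str) -> ArmLedger:
        if name not in ARMS:
            raise ValueError(f"unknown arm {name!r}")
        return getattr(self, name)


def _uniforms(seed: int, cycle: int, purpose: str, n: int) -> np.ndarray:
    ss = np.random.SeedSequence([int(seed), int(cycle), _PURPOSES[purpose]])
    return np.random.default_rng(ss).random(n)


def _empty_ledger(n: int, T: int) -> ArmLedger:
    b = lambda: np.zeros((n, T), dtype=bool)
    f = lambda: np.zeros((n, T), dtype=float)
    return ArmLedger(
        alive_start=b(), alive_end=b(), enrolled=b(),
        first_chd=b(), first_stroke=b(), recurrent=b(),
        cvd_death=b(), other_death=b(),
        costs={c: f() for c in COST_CATEGORIES}, utility=f(),
    )


def run_paired(
    cohort: pd.DataFrame,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> PairedResult:
    """Run the paired (policy vs status-quo) simulation over a cohort.

    Returns per-arm ledgers; both arms share identical random substreams
    keyed by (seed, cycle, draw purpose), with person identity given by
    row position.
    """
    if params is None:
        params = SimulationParams.from_config()
    n = len(cohort)
    T = int(params.max_cycles)
    if n == 0:
        raise ValueError("cohort is empty")

    # fixed covariates
    male = (cohort["sex"].to_numpy(dtype=object) == "male").astype(float)
    male_bool = male.astype(bool)
    race = cohort["race_ethnicity"].to_numpy(dtype=object)
    htn = cohort["hypertension"].to_numpy(dtype=float)
    base_cvd = cohort["cvd_history"].to_numpy(dtype=bool)
    base_chd_prev = cohort[["angina", "chd", "mi"]].astype(bool).any(axis=1).to_numpy()
    base_stroke_prev = cohort["stroke"].to_numpy(dtype=bool)

    participants = _uniforms(seed, 0, "participation", n) < params.participation_fraction

    eq_chd = params.equations["first_chd"]
    eq_stroke = params.equations["first_stroke"]
    eq_rec = params.equations["recurrent_cvd"]
    eq_cd = params.equations["cvd_death"]
    diet = params.diet_rr
    cost_p, util_p = params.costs, params.utilities
    w_rec = diet.recurrent_chd_weight
    rec_acute_cost = w_rec * cost_p.acute_cost_chd + (1 - w_rec) * cost_p.acute_cost_stroke
    rec_decrement = w_rec * util_p.decrement_chd + (1 - w_rec) * util_p.decrement_stroke

    ledgers = {name: _empty_ledger(n, T) for name in ARMS}
    state = {
        name: {
            "alive": np.ones(n, dtype=bool),
            "has_cvd": base_cvd.copy(),
            "chd_prev": base_chd_prev.copy(),
            "stroke_prev": base_stroke_prev.copy(),
        }
        for name in ARMS
    }

    for t in range(1, T + 1):
        u_first = _uniforms(seed, t, "first_event", n)
        u_type = _uniforms(seed, t, "first_type", n)
        u_rec = _uniforms(seed, t, "recurrent", n)
        u_cd = _uniforms(seed, t, "cvd_death", n)
        u_od = _uniforms(seed, t, "other_death", n)
        food_year, admin_year = intervention_cost(t, cost_p)

        for name in ARMS:
            st = state[name]
            led = ledgers[name]
            astart = st["alive"]
            if not astart.any():
                continue
            enrolled = participants & astart if name == "policy" else np.zeros(n, dtype=bool)

            rf = risk_factor_state(cohort, t, params.rules, enrolled, params.deltas)
            age, bmi, hba1c = rf["age"], rf["bmi"], rf["hba1c"]
            fv_delta = enrolled.astype(float) * params.deltas["fv_servings"]

            # first events among those without CVD history
            p_chd = expit(eq_chd.linear_predictor(age, male, bmi, hba1c, htn, race))
            p_str = expit(eq_stroke.linear_predictor(age, male, bmi, hba1c, htn, race))
            p_chd = adjust_probability(p_chd, diet.rr_chd(fv_delta, age))
            p_str = adjust_probability(p_str, diet.rr_stroke(fv_delta, age))
            p_first = 1.0 - (1.0 - p_chd) * (1.0 - p_str)
            first_ev = astart & ~st["has_cvd"] & (u_first < p_first)
            denom = p_chd + p_str
            share_chd = np.divide(p_chd, denom, out=np.full(n, 0.5), where=denom > 0)
            first_chd_ev = first_ev & (u_type < share_chd)
            first_str_ev = first_ev & ~(u_type < share_chd)

            # recurrent events require history at cycle start
            p_rec = expit(eq_rec.linear_predictor(age, male, bmi, hba1c, htn, race))
            p_rec = adjust_probability(p_rec, diet.rr_recurrent(fv_delta, age))
            rec_ev = astart & st["has_cvd"] & (u_rec < p_rec)

            has_cvd_new = st["has_cvd"] | first_ev

            # deaths: CVD death among those with (possibly new) history,
            # then non-CVD death among the rest
            p_cd = expit(eq_cd.linear_predictor(age, male, bmi, hba1c, htn, race))
            cvd_death_ev = astart & has_cvd_new & (u_cd < p_cd)
            q_bg = params.mortality.probability(age, male_bool)
            other_death_ev = astart & ~cvd_death_ev & (u_od < q_bg)
            alive_end = astart & ~cvd_death_ev & ~other_death_ev

            chd_prev = st["chd_prev"] | first_chd_ev
            stroke_prev = st["stroke_prev"] | first_str_ev

            # accrual (undiscounted; discounting happens at aggregation)
            frame = {
                "age": age, "sex": cohort["sex"].to_numpy(dtype=object),
                "bmi": bmi, "hba1c": hba1c,
                "hypertension": htn, "cvd_history": has_cvd_new.astype(float),
                "diabetes": np.ones(n), "race_ethnicity": race,
            }
            cov = _covariate_arrays(frame)
            hc = _linear_regression(
                cost_p.healthcare_regression,
                cov["age"], cov["male"], cov["bmi"], cov["hypertension"],
                cov["cvd_history"], cov["diabetes"], cov["race"],
            )
            hc = hc + cost_p.hba1c_cost_slope * np.maximum(0.0, hba1c - cost_p.hba1c_cost_reference)
            hc = np.maximum(hc, 0.0)

            util = _linear_regression(
                util_p.eq5d_regression,
                cov["age"], cov["male"], cov["bmi"], cov["hypertension"],
                cov["cvd_history"], cov["diabetes"], cov["race"],
            )
            util = util - util_p.decrement_chd * first_chd_ev
            util = util - util_p.decrement_stroke * first_str_ev
            util = util - rec_decrement * rec_ev
            util = np.clip(util, 0.0, 1.0)

            acute = (
                cost_p.acute_cost_chd * first_chd_ev
                + cost_p.acute_cost_stroke * first_str_ev
                + rec_acute_cost * rec_ev
            )
            prod = (
                cost_p.productivity_chd * chd_prev.astype(float)
                + cost_p.productivity_stroke * stroke_prev.astype(float)
            )

            j = t - 1
            led.alive_start[:, j] = astart
            led.alive_end[:, j] = alive_end
            led.enrolled[:, j] = enrolled
            led.first_chd[:, j] = first_chd_ev
            led.first_stroke[:, j] = first_str_ev
            led.recurrent[:, j] = rec_ev
            led.cvd_death[:, j] = cvd_death_ev
            led.other_death[:, j] = other_death_ev
            led.costs["intervention_food"][:, j] = enrolled * food_year
            led.costs["intervention_admin"][:, j] = enrolled * admin_year
            led.costs["healthcare"][:, j] = alive_end * hc
            led.costs["acute_event"][:, j] = acute
            led.costs["productivity"][:, j] = alive_end * prod
            led.utility[:, j] = alive_end * util

            st["alive"] = alive_end
            st["has_cvd"] = has_cvd_new
            st["chd_prev"] = chd_prev
            st["stroke_prev"] = stroke_prev

    return PairedResult(
        cohort=cohort, control=ledgers["control"], policy=ledgers["policy"],
        max_cycles=T, seed=int(seed), participants=participants,
    )


def _resolve_horizon(result: PairedResult, horizon) -> int:
    named = {"5y": 5, "10y": 10, "lifetime": result.max_cycles}
    if isinstance(horizon, str):
        if horizon not in named:
            raise ValueError(f"unknown horizon {horizon!r}; expected one of {sorted(named)}")
        h = named[horizon]
    else:
        h = int(horizon)
    if h < 1 or h > result.max_cycles:
        raise ValueError(f"horizon {h} exceeds the simulated {result.max_cycles} cycles")
    return h


def _person_totals(led: ArmLedger, h: int, rate: float) -> dict[str, np.ndarray]:
    disc = discount_factors(h, rate)
    out: dict[str, np.ndarray] = {
        "first_events": led.first_event[:, :h].sum(axis=1).astype(float),
        "recurrent_events": led.recurrent[:, :h].sum(axis=1).astype(float),
        "qalys": led.utility[:, :h] @ disc,
        "person_years": led.alive_end[:, :h].sum(axis=1).astype(float),
    }
    for cat in COST_CATEGORIES:
        out[f"cost_{cat}"] = led.costs[cat][:, :h] @ disc
    out["total_events"] = out["first_events"] + out["recurrent_events"]
    return out


def incremental_person_totals(
    result: PairedResult, horizon, discount_rate: float = 0.03
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-person incremental (policy minus control) discounted totals and
    survey weights; the basis for aggregation and within-run sampling
    variance."""
    h = _resolve_horizon(result, horizon)
    pol = _person_totals(result.policy, h, discount_rate)
    ctl = _person_totals(result.control, h, discount_rate)
    inc = {k: pol[k] - ctl[k] for k in pol}
    return inc, result.cohort["survey_weight"].to_numpy(dtype=float)


def aggregate(
    result: PairedResult,
    horizon,
    discount_rate: float = 0.03,
    mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Survey-weighted incremental totals at a horizon.

    Events averted are control-minus-policy counts; QALYs gained and cost
    streams are discounted policy-minus-control sums.  Healthcare savings
    combine the annual-prediction and acute-event streams; net costs
    follow the two reporting perspectives.
    """
    inc, w = incremental_person_totals(result, horizon, discount_rate)
    if mask is not None:
        inc = {k: v[mask] for k, v in inc.items()}
        w = w[mask]
    tot = {k: float(np.sum(w * v)) for k, v in inc.items()}
    weight_total = float(np.sum(w))

    first_averted = -tot["first_events"]
    recurrent_averted = -tot["recurrent_events"]
    total_averted = first_averted + recurrent_averted
    healthcare_savings = -(tot["cost_healthcare"] + tot["cost_acute_event"])
    productivity_savings = -tot["cost_productivity"]
    intervention_total = tot["cost_intervention_food"] + tot["cost_intervention_admin"]
    net_hc = intervention_total - healthcare_savings
    net_soc = net_hc - productivity_savings

    h = _resolve_horizon(result, horizon)
    return {
        "horizon_years": float(h),
        "weight_total": weight_total,
        "first_events_averted": first_averted,
        "recurrent_events_averted": recurrent_averted,
        "total_events_averted": total_averted,
        "events_averted_per_100k": 1e5 * total_averted / weight_total,
        "qalys_gained": tot["qalys"],
        "person_years_gained": tot["person_years"],
        "intervention_food_cost": tot["cost_intervention_food"],
        "intervention_admin_cost": tot["cost_intervention_admin"],
        "intervention_cost_total": intervention_total,
        "healthcare_savings": healthcare_savings,
        "productivity_savings": productivity_savings,
        "net_cost_healthcare": net_hc,
        "net_cost_societal": net_soc,
    }


def subgroup_aggregate(
    result: PairedResult,
    stratifier: str,
    horizon,
    discount_rate: float = 0.03,
) -> pd.DataFrame:
    """Per-stratum incremental results for a baseline stratifier column.

    Strata partition the cohort, so extensive quantities sum exactly to
    the overall aggregate.
    """
    if stratifier not in result.cohort.columns:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    values = result.cohort[stratifier].astype(str).to_numpy()
    rows = []
    for level in sorted(pd.unique(values)):
        mask = values == level
        row = aggregate(result, horizon, discount_rate, mask=mask)
        row["stratum"] = level
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[["stratum"] + [c for c in df.columns if c != "stratum"]]


def mean_followup_years(result: PairedResult, arm: str = "control") -> float:
    """Realized mean follow-up (years alive, capped at the cycle limit);
    diagnostic for the lifetime horizon."""
    led = result.arm(arm)
    return float(led.alive_end.sum(axis=1).mean())


def ledger_long_frame(result: PairedResult, horizon=None) -> pd.DataFrame:
    """Long-format per-person-per-year ledger (undiscounted accruals)."""
    h = result.max_cycles if horizon is None else _resolve_horizon(result, horizon)
    frames = []
    pid = result.cohort["person_id"].to_numpy(dtype=object)
    base_cvd = result.cohort["cvd_history"].to_numpy(dtype=bool)
    for name in ARMS:
        led = result.arm(name)
        has_cvd_end = base_cvd[:, None] | np.cumsum(led.first_event, axis=1).astype(bool)
        for j in range(h):
            active = led.alive_start[:, j]
            if not active.any():
                continue
            idx = np.nonzero(active)[0]
            state = np.where(
                ~led.alive_end[idx, j], "dead",
                np.where(has_cvd_end[idx, j], "cvd_history", "no_cvd"),
            )
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": pid[idx],
                        "year": j + 1,
                        "arm": name,
                        "alive_end": led.alive_end[idx, j].astype(int),
                        "enrolled": led.enrolled[idx, j].astype(int),
                        "first_chd": led.first_chd[idx, j].astype(int),
                        "first_stroke": led.first_stroke[idx, j].astype(int),
                        "recurrent_cvd": led.recurrent[idx, j].astype(int),
                        "cvd_death": led.cvd_death[idx, j].astype(int),
                        "other_death": led.other_death[idx, j].astype(int),
                        **{f"cost_{c}": led.costs[c][idx, j] for c in COST_CATEGORIES},
                        "utility": led.utility[idx, j],
                        "state": state,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
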
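# Methods

`produce_rx` implements an individual-level, annual-cycle state-transition
microsimulation of US adults aged 40–79 with both diabetes and food
insecurity, and a full cost-effectiveness analysis of offering this
population a produce prescription: free or discounted fruits and
vegetables prescribed through the health-care system, plus nutrition
education. The same cohort is simulated twice — with and without the
program — under common random numbers, and incremental cardiovascular
disease (CVD) events, quality-adjusted life-years (QALYs) and costs are
reported at 5-year, 10-year and lifetime horizons from a health-care and
a societal perspective.

## Synthetic eligible cohort

The generator reproduces the published baseline profile of the eligible
national population (6.5 million adults represented): mean (SD) age
58.2 (10.2) years on [40, 79], BMI 33.6 (7.95) kg/m², HbA1c 7.3 (1.95) %,
fruit 0.86 (1.08) and vegetables 1.30 (1.04) servings/day, 55.6% female,
74.8% hypertensive, 30.0% with CVD history (angina 15.8%, CHD 11.9%,
MI 12.8%, stroke 9.1%), and the published race/ethnicity, education,
income and insurance distributions; diabetes and food insecurity are
100% by construction.

Implementation choices:

* **Moment matching.** Published means/SDs describe the observed
  (truncated) variables, so latent truncated-normal parameters are solved
  numerically such that the realized truncated moments equal the printed
  values. Diet variables use moment-matched gamma marginals instead: the
  printed coefficient of variation of fruit intake (1.08/0.86 ≈ 1.26)
  exceeds 1, which no lower-truncated normal can attain, while a gamma is
  right-skewed and nonnegative — the realistic shape for intake data.
* **Dependence.** Continuous variables are joined by a Gaussian copula;
  the default latent correlation is 0.2 between BMI and HbA1c and 0
  elsewhere (the joint distribution of the source survey sample is
  unpublished; all dependence parameters are config-exposed). CVD-history
  probability rises log-linearly in age (0.06 log-odds/year by default)
  with the intercept calibrated by quadrature so the 30.0% marginal holds
  exactly in expectation.
* **CVD sub-flags.** Conditional on any CVD history, sub-conditions are
  drawn independently at their conditional prevalences; if none fires,
  the most prevalent one (angina) is forced so that "any history ⇔ at
  least one sub-flag" holds for every record. This slightly inflates the
  angina marginal (by roughly 3 percentage points); the overall 30%
  prevalence is unaffected.
* **Insurance.** The published insurance categories overlap (they sum to
  112.2% because dual eligibility also appears within Medicare/Medicaid
  counts); the generator renormalizes them proportionally into a proper
  five-category distribution and retains the raw values in config.
* **Survey weights.** Lognormal (σ = 0.5) and rescaled to sum to the
  represented total (6.5 million). Weights act purely as multipliers;
  survey design-based variance estimation (strata/PSUs) is not emulated.
* Records are complete by construction; the missing-data imputation of
  the source survey is not emulated.

## Intervention effects

Pooled effects of produce prescription programs, from random-effects
meta-analysis: fruit-and-vegetable intake +0.80 servings/day (95% CI
0.45–1.15), BMI −0.36 kg/m² (−0.55 to −0.16), HbA1c −0.63 percentage
points (−0.98 to −0.28). The pooling kernel is DerSimonian–Laird
(the conventional random-effects default): between-study variance
τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)), inverse-variance weights
1/(se² + τ²). Study-level rows are user input; a seeded synthetic
study-set generator stands in for the original study table, which is
not published in the main text.

For the probabilistic analysis each effect is treated as normal with SD
recovered from its CI, (upper − lower)/(2·1.96). The percentile sweep
moves all three deltas jointly toward benefit: for outcomes whose benefit
is a reduction (BMI, HbA1c) the percentile is mirrored, so the 2.5th
benefit percentile is the conservative CI bound of every outcome.

Effects are level shifts sustained while enrolled; all benefits cease on
disenrollment (conservative no-persistence assumption). Participation is
drawn once at baseline (Bernoulli at the configured fraction, default
1.0, sensitivity 0.5) and fixed thereafter.

## Risk engine

Annual transition probabilities come from logistic equations over age,
sex, race/ethnicity, BMI, HbA1c and hypertension, centred at age 60,
BMI 30, HbA1c 7. The governing equations of the source model are
unpublished; the shipped coefficients are synthetic stand-ins calibrated
so that, near the cohort centre, first CVD events run ≈1–3%/year and
recurrent events ≈3–6%/year — plausible for this high-risk population.
Every coefficient is configuration and can be replaced with fitted
values; all tests of this layer are structural (identities, monotonicity,
oracle arithmetic), not event-count replication.

* **First events.** CHD and stroke equations jointly define the
  first-event probability, 1 − (1−p_CHD)(1−p_stroke), and the event type
  is drawn from their relative contribution — the CHD/stroke mixture is
  therefore configurable through the two equations.
* **Recurrent events** use a single pooled equation and require CVD
  history at cycle start.
* **Diet pathway.** A change of Δ servings/day multiplies risk by
  RR = exp(a(age)·Δ·ln RR₁), with RR₁ = 0.95 (CHD) and 0.96 (stroke) per
  serving by default and a piecewise age attenuation a(age) ∈
  {1.00, 0.85, 0.70, 0.55} for <55, 55–64, 65–74, 75+, shrinking the
  log-RR toward the null at older ages. RRs act on annual probabilities
  on the rate scale, p′ = 1 − (1−p)^RR, which preserves {0, 1}, agrees
  with p·RR to first order in small p, and cannot leave [0, 1]. Recurrent
  events use a CHD/stroke log-RR mixture (default weight 0.6 CHD).
* **BMI/HbA1c pathways** operate through the equations' coefficients.
* **Mortality.** CVD death has its own logistic equation (applied to
  those with CVD history, including a same-cycle first event); non-CVD
  death uses an age–sex annual-probability table, by default a synthetic
  Gompertz life table q(a) = 5.4·10⁻⁵·e^{0.09a} for men (women at 65%),
  elevated relative to the general population to reflect diabetes. A CSV
  table (age, sex, annual_probability) can be supplied instead.
* **Within-cycle order.** Risk-factor update → first-event draw →
  recurrent draw → CVD death → non-CVD death → accrual. Death precludes
  subsequent same-cycle events. Simulation stops at death or 60 cycles.

## Costs and utilities (2021 USD)

* **Program costs.** Food cost accrues at the redeemed value, $32/person/
  month ($384/year); the offered value $42/month ($504/year) is retained
  for reporting. Administrative cost is 50% of food cost in program year
  1 (launch premium: one third of total cost) and s/(1−s)·food thereafter
  with steady-state share s = 15% of total (presets 8%, 21.3%, 23%). The
  launch premium applies in calendar year 1 of the program, not per
  enrollee.
* **Healthcare costs.** A linear prediction over age, sex,
  race/ethnicity, BMI, diabetes, hypertension and CVD history (synthetic
  stand-in coefficients for the unpublished expenditure-survey
  regression), plus an HbA1c term — $1,150/year per point above 7.0 —
  that models only the glycemia-dependent, non-CVD diabetes costs.
  CVD-dependent spending enters solely through the CVD-history
  coefficient and acute event costs, so HbA1c improvements cannot
  double-count averted CVD costs. Predictions are floored at 0.
* **Acute event costs** are config scalars ($21,000 CHD, $17,500 stroke
  by default); recurrent events, whose type is pooled, cost the
  CHD/stroke mixture-weighted average.
* **Productivity costs** accrue per prevalent case-year ($1,100 CHD,
  $1,700 stroke defaults) and are additive when both are present.
* **Utilities.** EQ-5D predicted from the same covariate set (synthetic
  stand-in), minus one-year decrements of 0.055 for an acute CHD event
  and 0.3 for an acute stroke (mixture-weighted for pooled recurrent
  events), clamped to [0, 1].
* **Accrual conventions** (the source text does not state them): program
  cost accrues to enrollees alive at cycle start; acute event costs to
  everyone with an event, including decedents; annual healthcare,
  productivity and utility to cycle survivors. Dead person-years
  contribute nothing.
* **Discounting.** 3%/year for costs and QALYs, year 1 undiscounted
  (timing convention chosen here; the source does not state one).

## Paired simulation and common random numbers

Both arms consume identical uniform substreams keyed by (seed, cycle,
draw purpose), with person identity fixed by row position, so the two
arms are a coupled pair: with zero effect deltas the ledgers coincide
exactly, giving zero incremental variance (not merely zero mean), and
all incremental differences are attributable to the intervention.
No half-cycle correction is applied (annual accrual at cycle end).

Aggregation multiplies per-person discounted totals by survey weights.
Events averted are control-minus-policy counts; total averted = first +
recurrent averted by construction. Net cost (health-care perspective) =
intervention costs − healthcare savings; societal further subtracts
productivity savings. Subgroup results are computed by masking persons,
so strata sum exactly to the overall totals.

## Uncertainty analysis

* **PSA.** Each of the (default 1000) draws samples every uncertain
  parameter — effect triple, diet log-RRs, redeemed monthly value, acute
  and productivity costs, HbA1c cost slope, EQ-5D intercept and
  decrements — from draw-id-keyed substreams, then re-runs the paired
  simulation on a stream shared across draws. Between-draw spread thus
  isolates parameter uncertainty; cohort-sampling uncertainty enters as
  the within-draw variance of each weighted total (with-replacement
  estimator, n/(n−1)·Σ(wᵢxᵢ − mean)²). Rubin's rule combines the two:
  total variance = mean within-draw variance + (1 + 1/m)·between-draw
  variance; 95% uncertainty intervals are mean ± 1.96·√total.
* **ICERs** are ratio-of-means (mean net cost / mean QALYs gained) with
  dominance labels: cost-saving (ΔQALY > 0, Δcost < 0), dominated
  (ΔQALY < 0, Δcost > 0), undefined (ΔQALY = 0).
* **CEAC.** Probability that net monetary benefit WTP·ΔQALY − Δcost > 0
  across draws; evaluated at $50,000 and $150,000/QALY by default.
* **Threshold analysis.** Program costs enter linearly and have no
  feedback on health states, so the ICER is monotone in the monthly cost;
  bisection finds the total monthly cost (redemption + admin) at which
  the ICER crosses the WTP threshold, to $0.10/month, reporting
  "unbounded" if no crossing exists below 10× the current cost.

## Problem sizes and numerical choices

Generator calibration checks use 50,000-person cohorts; the paired-null,
monotonicity and threshold checks use 2,000–5,000 persons, and the PSA
property checks 100 draws — scales at which the documented invariants
are sharp (many are exact identities independent of n). Degenerate
inputs are handled explicitly: zero-SD marginals collapse to point
masses, zero-probability categories never fire, p ∈ {0, 1} survive
rate-scale adjustment exactly, ties in the first-event type split are
broken at probability one half, and the CVD-history intercept calibration
uses 200-node Gauss–Legendre quadrature with Brent root finding.

## Limitations

* Risk-equation, cost-regression, utility-regression, mortality, acute
  and productivity cost defaults are synthetic stand-ins — structurally
  faithful, not fitted. Absolute event counts, dollars and ICERs from
  the defaults characterize the machinery, not the US population;
  replace the config coefficients with fitted values for substantive
  estimates.
* The generator matches published marginals but invents the dependence
  structure; passing calibration tests demonstrates marginal fidelity,
  not joint-distribution fidelity.
* No within-year event timing, no family spillover effects, no
  institutional (nursing-home) costs, no smoking or lipid sub-models,
  and diabetes incidence is inert (all simulated individuals have
  diabetes at baseline).
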
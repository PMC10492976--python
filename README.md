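# produce-rx

State-transition microsimulation and cost-effectiveness analysis of
**produce prescription programs** — health-system provision of free or
discounted fruits and vegetables — for US adults aged 40–79 with both
diabetes and food insecurity.

The package is aimed at health-economics and nutrition-policy modelers.
It provides:

* a **synthetic cohort generator** that reproduces the published
  baseline profile of the eligible national population (survey-weighted
  marginals for demographics, insurance, risk factors and CVD history,
  joined by a Gaussian copula);
* **random-effects meta-analysis** (DerSimonian–Laird) of study-level
  intervention effects on fruit/vegetable intake, BMI and HbA1c;
* a **paired annual-cycle microsimulation**: every person is followed
  until death or 60 years, once with and once without the program, under
  common random numbers, with logistic annual transition probabilities
  (first CHD/stroke, recurrent CVD, CVD death, non-CVD death), a
  log-linear diet–disease relative-risk pathway
  RR = exp(a(age)·ΔFV·ln RR₁) applied on the rate scale
  p′ = 1 − (1−p)^RR, and BMI/HbA1c pathways through the equations;
* a **cost and QALY layer**: program food/admin costs ($32 redeemed of
  $42 offered per month; admin 15% of total at steady state, 50% of food
  cost in year 1), individually predicted healthcare costs with an
  HbA1c-dependent non-CVD diabetes component, acute event and
  productivity costs, EQ-5D utilities with one-year acute decrements
  (CHD −0.055, stroke −0.3), all discounted at 3%/year;
* a **CEA layer**: ICER = Δcost/ΔQALY with dominance labels,
  probabilistic sensitivity analysis with Rubin's-rule uncertainty
  intervals (total variance = mean within-draw + (1+1/m)·between-draw),
  cost-effectiveness acceptability curves, effect-size percentile
  sweeps, subgroup stratification, and a break-even monthly-cost
  threshold analysis.

The default risk-equation, cost-regression and utility-regression
coefficients are documented synthetic stand-ins (see
[`docs/methods.md`](docs/methods.md)); every parameter is plain
configuration and can be overridden from YAML/JSON.

## Worked example

```python
import produce_rx as prx

spec = prx.default_population_spec()                 # published baseline marginals
cohort = prx.generate_cohort(spec, n=5000, seed=1)

params = prx.SimulationParams.from_config()      # base-case parameter bundle
result = prx.run_paired(cohort, params, seed=1)  # policy vs status quo
life = prx.aggregate(result, "lifetime")

print(f"events averted (per 100k): {life['events_averted_per_100k']:,.0f}")
print(f"QALYs gained:              {life['qalys_gained']:,.0f}")
print(f"net cost, healthcare:      ${life['net_cost_healthcare']/1e9:,.2f}B")
print(f"ICER (healthcare):         {prx.icer(life['net_cost_healthcare'], life['qalys_gained']):,.0f} $/QALY")
print(f"threshold monthly cost:    ${prx.threshold_monthly_cost(result, wtp=150000.0):,.2f}/month")
```

prints

```
events averted (per 100k): 6,945
QALYs gained:              936,350
net cost, healthcare:      $15.15B
ICER (healthcare):         16,184 $/QALY
threshold monthly cost:    $163.88/month
```

Reading: over the lifetime horizon this run averts about 6,900 CVD
events per 100,000 eligible adults and gains roughly 0.94 million QALYs
across the 6.5 million people the weighted cohort represents. The
program costs about $15B more than it saves in healthcare spending, or
about $16,000 per QALY gained — well under conventional $50,000–$150,000
willingness-to-pay thresholds — and would stay under $150,000/QALY up to
a total program cost of about $164 per person-month. Absolute magnitudes
reflect the synthetic default coefficients; the structure, identities
and uncertainty machinery are what the package warrants.

The same pipeline is scriptable from the shell:

```bash
produce-rx generate --n 5000 --seed 1 --out cohort.csv
produce-rx simulate --cohort cohort.csv --seed 1 --out results/
produce-rx psa --cohort cohort.csv --draws 1000 --seed 1 --out results/
produce-rx cea --cohort cohort.csv --seed 1 --wtp 50000,150000 --out cea.json
```

## Layout

```
src/produce_rx/
  config.py       # every default parameter, YAML/JSON override loading
  population.py   # synthetic survey-weighted cohort generation + CSV I/O
  meta_effects.py # DL pooling, effect distributions, percentile sweeps
  risk_engine.py  # logistic transition equations, diet RRs, trajectories
  econ_qaly.py    # program/healthcare/event/productivity costs, EQ-5D, discounting
  engine.py       # paired common-random-number microsimulation + aggregation
  cea.py          # ICER, PSA + Rubin's rule, CEAC, sweep, threshold analysis
  cli.py          # produce-rx generate / simulate / psa / cea
```
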
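# her2cea

A Markov cohort cost-effectiveness model for **sequential trastuzumab-based
therapy in HER2-positive metastatic breast cancer**, parameterised for the
Taiwanese payer setting (2018 USD).  It is written for health-economics
researchers who need a reproducible, testable implementation of the full
pipeline: vial-based drug costing under wastage and no-wastage conventions,
log-logistic survival transitions, weekly-cycle cohort simulation with
QALY/cost discounting, ICER frontier construction, and deterministic and
probabilistic sensitivity analysis with CEAC output.

## The model in brief

A strategy is an ordered sequence of treatment lines (e.g.
PTH → T-DM1 → trastuzumab+lapatinib).  States are
`PF_line1 … PF_lineL`, `PD`, `Dead`.  Each line's PFS and OS follow a
log-logistic survival function

    S(t) = 1 / (1 + (λt)^γ),        median = 1/λ,

on the line's own clock (clocks reset at each new line; the engine tracks
occupancy by time-in-line so per-cycle transition probabilities
tp(k) = 1 − S((k+1)Δ)/S(kΔ) are exact).  Costs accrue from weekly regimen
streams (whole-vial or fractional-vial acquisition costs, recurring
monitoring, one-time adverse-event and palliative costs); QALYs from state
utilities, an additive response increment, and one-time progression and
adverse-event disutilities; both discounted at 0.000662 per week.
Strategies are compared by ICER = Δcost/ΔQALY along the dominance-adjusted
efficiency frontier; parameter uncertainty propagates through gamma/beta/
uniform distributions into cost-effectiveness acceptability curves from
net monetary benefit w·QALY − cost.  See `docs/methods.md` for the full
account, including the no-wastage vial-charging rule derived from the
published worked figures.

## Worked example

```python
import her2cea as h

ps = h.load_parameters(scenario="base_case")   # packaged, validated inputs
drugs = h.load_drugs()

dose = h.compute_dose(drugs["docetaxel"], ps.patient)   # 75 mg/m2 × 1.59 m2
combo = h.vial_cost_wastage(dose, drugs["docetaxel"].vials)
print(dose, combo.counts, combo.cost)
# 119.25 ((20.0, 2), (80.0, 1)) 765.86
```

The 119.25 mg dose is covered cheapest by one 80 mg vial plus two 20 mg
vials at **$765.86** per administration — the published wastage-scenario
figure.  The full four-strategy comparison:

```
$ her2cea run --out results_run
   strategy      cost     qaly       ly
pth_tdm1_tl 117083.27 1.151746 2.147691
  pth_lx_tc 117619.71 1.291383 2.272131
 th_tdm1_tl  76961.65 1.074818 2.052228
   th_lx_tc  77568.85 1.217415 2.179402
   strategy          cost     qaly       ly  dominated  extended_dominated          icer
 th_tdm1_tl  76961.648176 1.074818 2.052228      False               False           NaN
   th_lx_tc  77568.853412 1.217415 2.179402      False               False   4258.186504
pth_tdm1_tl 117083.272489 1.151746 2.147691       True               False           NaN
  pth_lx_tc 117619.710257 1.291383 2.272131      False               False 541462.926439
```

Reading the table: over a 10-year horizon at baseline inputs,
TH → T-DM1 → T+L is the cheapest strategy; stepping up to
TH → lapatinib+capecitabine → T+C buys 0.14 QALYs at ≈$4,258/QALY;
PTH → T-DM1 → T+L is strictly dominated (costlier and less effective than
a TH-led sequence); and the most effective strategy, PTH → L+X → T+C,
costs ≈$541,000 per additional QALY.  These are properties of the packaged
baseline inputs and the documented engine assumptions, not a reproduction
of any published headline result.  `run` also writes
`calibration_report.csv` with each curve's implied median survival (1/λ)
so the time-unit assumption can be audited.

Other commands: `her2cea costs REGIMEN` (weekly cost stream),
`her2cea dsa` (tornado CSV), `her2cea psa --psa-draws N --seed S`
(PSA draws + CEAC CSVs), `her2cea fit IPD.csv --seed S` (parametric
survival fits with AIC/BIC selection).  CSV schemas: strategy results
(strategy, cost, qaly, ly); ICER table (+ dominance flags, icer); tornado
(parameter, outcome_low, outcome_high, range); PSA draws (draw, strategy,
cost, qaly, ly); CEAC (wtp, strategy, probability); cost streams
(week, cost); calibration (regimen, endpoint, shape, scale,
implied_median).

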
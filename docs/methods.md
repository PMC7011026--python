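# Methods

## Model overview

`her2cea` implements a weekly-cycle Markov cohort model of sequential
HER2-targeted therapy for metastatic breast cancer, in the Taiwanese
payer setting (all prices 2018 USD).  A strategy is an ordered sequence of
treatment lines (e.g. pertuzumab+trastuzumab+docetaxel → T-DM1 →
trastuzumab+lapatinib).  The state space for an L-line sequence is
`PF_line1 … PF_lineL` (progression-free, on treatment), `PD` (progressed
after the final line, off active treatment) and `Dead`.

Each line carries its own progression-free-survival (PFS) and overall-
survival (OS) curve, both log-logistic:

```
S(t) = 1 / (1 + (λ t)^γ),   γ (shape) > 0, λ (scale) > 0,  median = 1/λ.
```

This parameterisation was chosen over the alternative `1/(1 + λ t^γ)`
because the packaged scale values then imply medians consistent in rank
with the source trials (e.g. T-DM1 PFS median 1/0.104256 ≈ 9.6 time
units); the functional form is explicit in `survival.survival_at` and
nowhere assumed implicitly.  Per-cycle transition probabilities are
conditional survival increments, `tp(k) = 1 − S((k+1)Δ)/S(kΔ)`, which
satisfy the telescoping identity `Π_{j<k}(1−tp(j)) = S(kΔ)` exactly — a
property the test suite checks to 1e-12 for every packaged curve.

**Time unit.** The published shape/scale values do not state their time
unit, and the implied medians are plausible in months for first-line OS
but in weeks for later-line PFS.  The engine stores a per-curve time unit
defaulting to model weeks, supports λ-rescaling (`λ' = λ·ratio`), and the
`run` command writes a calibration report of implied medians so users can
audit the assumption.  No unit conversion is silently applied.

**Line clocks.** Trial curves describe time from the start of that line of
therapy, so each line's clock resets on entry.  A cohort model with
resetting clocks is not memoryless at the state level; the engine
therefore tracks occupancy *by time already spent in the line*
(age-structured arrays), making the per-cycle hazards exact rather than an
average over entry cohorts.  Progression from the final line enters `PD`
carrying the final line's clock, and the final line's OS curve keeps
governing death there (the publication does not provide a separate
post-progression survival).

**Competing risks.** Within a cycle, death (from the line's OS curve) is
applied first and progression applies to survivors,
`tp_prog = tp_prog_raw × (1 − tp_death)`; an independent-complement
convention is available via `ModelConfig(overlap="independent")`.  At
weekly resolution the two agree to a few percent.

**Cycle length and half-cycle correction.** The default cycle is Δ = 1
week; halving Δ changes life-years by well under 1% (tested).  A
trapezoidal half-cycle correction is available but off by default — with
weekly cycles it shifts QALYs by only a few percent, driven mostly by the
front-loaded first-cycle hazards of the γ < 1 log-logistic curves.

**Horizon.** Default 520 weeks (10 years), configurable; the source tables
do not state one.

## Costs

Acquisition costs are computed from dosing rules (per kg, per m², flat, or
oral daily) for the reference patient (58.1 kg, 1.59 m²) and a vial
catalog:

* **Wastage scenario** — the cost of an administration is the cheapest
  multiset of whole vials covering the dose (exhaustive bounded search,
  ties broken by fewer vials, then larger total strength).  The optimiser
  is tested against an independent brute-force enumeration on randomised
  catalogs.
* **No-wastage scenario** — the same vial combination is opened, but the
  smallest-strength vial is charged pro rata (`remainder/strength`).
  This rule — rather than a global minimisation over fractional covers —
  reproduces every published no-wastage figure, including the docetaxel
  $760.88 (= 500.50 + 132.68 + 0.9625 × 132.68) that a naive
  `1.49 × 500.50` reading cannot explain, and the T-DM1 $3754.05
  (1×160 mg + 0.4916×100 mg).  Published figures that round the vial
  fraction before pricing (trastuzumab 1.056 / 0.792 vials) are
  reproducible through an explicit `fractions=` override.
* Oral drugs round up to whole tablets (capecitabine 2000 mg/m² →
  3180 mg → 7×500 mg tablets, $22.61/day); lapatinib is a flat
  1500 mg/day at $97.74.

Regimen schedules are data (`data/regimens.yaml`), expanded to weekly cost
vectors.  They encode the published administration weeks verbatim,
including two quirks of the source schedule: the post-docetaxel phase of
PTH/TH runs on weeks 17, 20, 23, … (shifted one week against the
1, 4, …, 16 docetaxel phase), and trastuzumab+capecitabine charges the
loading-dose price on weeks 3, 6, 9, … alongside the maintenance price on
weeks 4, 7, 10, ….  Every published weekly total in both scenarios is a
frozen test expectation.

Monitoring ("background") costs are charged on the first week of each
recurrence interval on the line clock: physician fee ($8.15) and blood
work ($6.27) every 3 weeks, CT every 9 weeks, echocardiogram ($119.05)
every 13 weeks while on HER2-targeted therapy.  Where the source lists two
values for the same item (echocardiogram $99.52 vs $119.05; blood work
$22.98 vs $6.27), the value carrying sensitivity-analysis bounds is used
and the alternative is recorded in the parameter's note field.

Grade ≥3 adverse events are one-time expected costs: per-regimen totals
equal Σ incidence × unit management cost, with incidences back-derived
from the published per-patient cost cells (they recover clean trial
proportions, e.g. 0.129 for T-DM1 thrombocytopenia).  The weekly AE
probability applies to the on-treatment (PF) mass; expected event mass
also accrues the one-time AE disutility.  A one-time palliative/end-of-
life cost ($7185.72) is charged on the mass entering `Dead`.

## Utilities and discounting

Progression-free utility 0.785746 plus an additive treatment-response
increment 0.061 (applied to a configurable responder fraction, default
1.0 — the source defines no response state); progressed utility 0.538; a
one-time −0.248 disutility on every progression transition.  QALYs accrue
as occupancy × utility × Δ/52.18 per cycle.  Costs and QALYs are
discounted at the weekly rate 0.000662, factor `(1+r)^(−week)`;
life-years are reported undiscounted.

## Parameter registry and sensitivity analysis

Every input lives in scenario-keyed CSVs with DSA bounds, PSA SD and
distribution.  Conventions implemented and validated:

* DSA bounds: `baseline × (1 ∓ rule)` for ±25%/±50% rows.
* PSA SD: `(high − low)/4` (bounds read as a ±2 SD interval).  This rule
  reproduces every printed SD for rule-derived and "calculated" rows;
  survival shape/scale rows carry regression standard errors instead and
  are exempt from the rule.  One printed SD (CT scan, 317.85714) is a
  typo for 17.85714 under this rule and is stored corrected with
  provenance `derived`.
* PSA distributions: gamma for costs (moment-matched shape/rate:
  `shape=(m/s)²`, `rate=m/s²`), beta for utilities/probabilities
  (moment-matched α, β), uniform(low, high) for disutilities and the
  discount rate.  The "negative beta/uniform" disutility row is sampled
  uniform by default.  Draws are independent across parameters (no
  correlation structure is published).

The ICER frontier removes strict dominance, then extended dominance
(a strategy whose ICER exceeds the next segment's), and reports
Δcost/ΔQALY along the surviving frontier; zero-ΔQALY ties are reported as
dominance, never divided.  The construction is tested against an
independent greedy minimum-ICER oracle on random strategy sets.  Tornado
output orders parameters by the range of a caller-chosen scalar outcome
(default: the ICER between two named strategies), because with four
strategies "the" ICER is otherwise ambiguous.

## Synthetic data

The published inputs are curve parameters, not patient records, so the
fitting stage is exercised on simulated cohorts: event times by inverse-CDF
sampling `t = (1/λ)(u/(1−u))^{1/γ}`, censoring uniform on `(0, t_max)`
with `t_max` solved numerically so the expected censored fraction matches
the target rate.  This emulates administrative right-censoring only — not
informative censoring, curve-digitisation error, or covariate structure —
so recovery tests certify the estimator, not the fidelity of any real
reconstructed dataset.  Default study conditions for recovery and model
selection follow the published fitting setup: five families (exponential,
Weibull, Gompertz, lognormal, log-logistic) fitted by right-censored MLE
and compared on AIC (BIC as tie-break); at n = 2000 with 20% censoring
the generating log-logistic family is selected in ≥90% of seeds, and at
n = 500 the median relative error of (γ̂, λ̂) is ≤10% over 50 seeds.

## Numerical choices

* MLE in transformed (log-)parameter space, Nelder–Mead, 5 jittered
  restarts, tolerance 1e-8; non-finite likelihoods get a large finite
  penalty to keep the simplex well-defined.  The log-logistic likelihood
  is written with `logaddexp` for overflow safety.  Fits agree with
  lifelines' `LogLogisticFitter` to ~1e-3 relative.
* The vial optimiser bounds each option's count by `ceil(dose/strength)`;
  with at most a handful of options the search is exact and instantaneous.
* Occupancy conservation is asserted inside the engine every cycle at
  1e-9; trace sizes are O(horizon²) floats per line (a few MB at the
  default horizon).
* Problem sizes in the test and acceptance suites (50 recovery seeds at
  n = 500, 20 selection seeds at n = 2000, 10⁴ moment-matching draws,
  randomised oracle sweeps of 100–200 cases) were chosen as the smallest
  sizes at which the statistical assertions are stable.

## Known limitations

* The headline ICER/CEAC results of the companion evaluation are not
  published in the data source, so the packaged defaults reproduce inputs
  and worked cost figures, not end-result tables; the four default
  sequences are a documented assumption, fully user-definable as data.
* No dose reductions, delays, relative-dose-intensity or adherence
  modelling; no AE-specific health states; no post-progression survival
  distinct from the final line's OS curve; no parameter correlation in
  PSA; no value-of-information analysis.
* Printed-value fidelity is to the cent for costs; where the source is
  internally inconsistent (duplicate unit costs, the monthly-visit product
  8.15 × 0.69) the convention adopted is recorded in the parameter notes
  and above.
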
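# Methods

This note documents the model, its parameters, the synthetic-data design,
the numerical choices, and the limitations of the `simisim` package. It is
the package's own account of its science; every number quoted here is
computed by the test suite or `scripts/acceptance.py`.

## Model and assumptions

The unit of analysis is the **seriously ill patient-year**: a person-year of
a resident-scheme (URRBMI) insuree whose annual serious-illness expense —
the self-payment under insurance plus the deductible portion, i.e. the part
a serious-illness scheme (SIMIS) can reimburse — strictly exceeds the
10,000-yuan screening threshold. Within-year visit-level detail is not
modelled; each patient-year carries one visit-type label (only-outpatient
OOMS, only-inpatient OIMS, or both BOIMS).

The simulation composes five mechanisms per gender × age-band cell and year:

1. **Insured population.** An exponential trend `N_t = a·e^{b(t−t0)}` is fit
   to a registered-population series by ordinary least squares on log
   counts; the eligible population (total minus a configurable, linearly
   trending employee-scheme share) is scaled by a participation rate
   (default 0.97). For the Shanghai scenario the package ships the
   published 2016–2025 insured/uninsured projection as a fixture, used
   verbatim: the published series is not monotone and cannot be reproduced
   by any single exponential fit, so fixture mode is authoritative there.
2. **Admission.** The expected patient count is
   `insured × rate/100`, realised as a Poisson draw (independent rare
   events across a large cohort) or deterministic rounding for exact tests.
   Observed rates are screened patients over insured; forecast years add a
   constant annual increment equal to the mean annual rise over the
   observed window excluding its final transition
   (`(rate[last−1] − rate[first]) / (last − first)`), floored at zero.
3. **Visit type.** A categorical draw from the cell-year OOMS/OIMS/BOIMS
   triple. Observed triples are empirical frequencies; forecast triples
   move each probability by its mean annual change over consecutive
   observed pairs, then are clipped to [0, 1] and renormalised, which keeps
   them valid distributions by construction.
4. **Annual total expense.** Two uniforms per patient: `ran01` selects one
   of four expense-level strata (equal ¼ interval masses by default,
   configurable to empirical masses), and
   `cost = (ran02 + 0.5) × mean_stratum,year`, so the cost is uniform on
   [0.5, 1.5] × mean and unbiased for the stratum mean. Stratum means roll
   forward multiplicatively, `mean_{y+1} = mean_y (1 + g)`, with `g` the
   arithmetic mean of the 2013–2014, 2014–2015 and 2015–2016 growth rates;
   one constant `g` per stratum is applied to every forecast year, because
   no later observations exist from which to re-estimate it.
5. **Payment decomposition.** Fixed per-stratum share triples split the
   total into fund payment, serious expense `S` and total self-payment,
   fen-exact via largest-remainder rounding on integer fen. Shares are the
   2014–2016 means of yearly aggregate ratios (fund/total and
   serious/total per year, then averaged); the residual self share is
   floored at zero with renormalisation. A payment scheme then splits `S`
   into the SIMIS payment and the remaining self-payment under SIMIS;
   schemes never alter consumption.

Expense **strata** are gender (2) × age band (<60 / ≥60) × expense level
(4), where the level is the within-(gender, age-band, year) quartile group
of annual totals — 16 strata, crossed with the three visit types for the
cost and share models. Quartiles are rank-based with stable tie-breaking,
so the four groups within a cell-year differ in size by at most one.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| screening threshold | 10,000 | yuan | entry criterion for "seriously ill"; strict inequality |
| large-expense scheme | threshold 25,000, rate 0.60, no ceiling | yuan / fraction | threshold anchored to the 2015 rural per-capita disposable income (25,520 yuan); payment base is the excess over the threshold |
| disease-based scheme | threshold 0, rate 0.60, no ceiling | — | payment base is the full serious expense, restricted to disease-eligible patients |
| participation rate | 0.97 | fraction | basic-insurance participation in Shanghai |
| level interval masses | ¼ each | — | the level definition is the quartile partition; empirical masses configurable |
| financing amount | 190 | million yuan/yr | scenario fixture for the sustainability flag |
| disease-eligibility prevalence | 0.712 | fraction of patients | calibrated so the disease-based scheme reaches ≈18,000 of the ≈25,000 2020 patients |

The **payment base** of the large-expense scheme defaults to
`rate × (S − threshold)`: published minimum annual payments of 0.02–2.09
yuan are only producible if the payment scales with the excess; a
full-serious-expense base is available as an option.

## The Shanghai reference scenario

`simisim.scenario` packages the published parameter tables (insured
projection 2016–2025, admission rates, visit-type mixes, six printed BOIMS
cost strata, six printed fund-share strata, annual payment totals, per-capita
SIMIS payments) and completes them into a full parameter set. Completions
are **synthetic scenario fixtures**, not estimates:

* forecast admission rates 2018–2024 interpolate the printed 2017 and 2025
  values at a constant annual increment (the printed forecasts are not
  themselves outputs of the stated increment formula, so the printed
  anchors are taken as authoritative);
* the ten unprinted BOIMS strata scale the fully printed male/<60 level
  profile to the two printed anchor strata; OOMS/OIMS means scale BOIMS
  means by the published 2020 per-capita cost ratios (0.713, 1.261);
* unprinted fund shares use level-wise offsets to the printed anchors; the
  serious-expense share (0.285 everywhere) is calibrated to the published
  payment composition;
* the insured population's age mix is unpublished but strongly identified
  by patient volume, because ≥60 admission rates are roughly tenfold the
  <60 rates; the ≥60 share (≈0.0098) is solved at load time so the
  insured-weighted 2020 rate matches the published 2020 patient count,
  with genders split evenly.

With this scenario the simulated 2020 patient volume falls within 1% of the
published 25,267. The published per-capita costs (e.g. ≈137,000 yuan for
BOIMS in 2020) are, however, not derivable from the printed stratum means
under any level masses that include the printed low strata — the published
tables are internally inconsistent there — so simulated per-capita costs
and totals (≈70,000 yuan, ≈17.7 hundred-million yuan in 2020) are reported
as computed and no attempt is made to force them toward the published
aggregates. Beneficiary counts under the large-expense rule depend directly
on these cost levels and inherit the discrepancy.

## Synthetic claims generator

The generator emulates a 2% claims sample of the insured population over a
2011–2016 calibration window: default cohort 67,418 persons (2% of the 2016
insured), cell marginals equal to the scenario's calibrated mix, the
published observed admission rates and visit mixes (back-cast by their
2016→2017 change), the completed stratum means back-cast at their growth
rates, and the completed share triples applied deterministically. Claims
are person-year aggregates with the same (u + 0.5) × mean cost law the
simulator uses, so generator and simulator share one law — no other
within-year expense distribution is identified by the study design, and the
uniform-around-mean law is an explicit artifact choice.

Two features matter for interpreting the recovery tests:

* **Level assignment.** By default each claim's expense level is drawn
  independently (`iid`, the two-random-number rule). Because estimation
  re-derives levels as within-cell rank quartiles, iid realized level
  counts deviate from exact quarters by O(√n), leaving an O(1/√n)
  contamination bias in re-estimated stratum means that never becomes
  negligible relative to their standard errors. The generator therefore
  also offers `quota` mode — exactly a quarter (±1) of each cell-year's
  claims per level, which is the quartile definition itself — and the
  recovery tests use it together with well-separated level means (adjacent
  mean ratios above 3, so the [0.5, 1.5] × mean supports are disjoint).
  Under those identifiability conditions every estimated parameter is
  unbiased for its generating value and the 3-standard-error recovery
  suite passes at 50,000 person-years. With the overlapping default means
  calibrated to the published strata, the quartile estimator instead converges to
  the quartile means of the pooled mixture — a property of the estimand,
  not an implementation error.
* **What passing recovery shows.** Admission rates, visit-type
  probabilities and share triples are recovered unconditionally; stratum
  means and growth rates are recovered under the identifiability
  conditions above. Real claims data would add skewed within-stratum cost
  distributions, longitudinal persistence of illness, and behavioural
  responses to policy, none of which the generator emulates — passing
  tests certify the estimation/simulation machinery, not those features of
  real data.

## Numerical choices

* Money is kept at full precision internally and rounded to 0.01 yuan (one
  fen) at storage; all proportional splits use largest-remainder rounding
  on integer fen, so decomposition identities hold exactly, and validators
  accept a 0.01-yuan tolerance for data read from text.
* Each (cell, year) owns the random substream `[seed, gender, age_band,
  year]`; within it one count draw is followed by four uniforms per patient
  in fixed order (visit, ran01, ran02, disease flag). This makes the full
  pipeline reproducible from one root seed, makes adding a cell a no-op for
  other cells' draws, and lets a naive per-patient loop reproduce the batch
  engine draw for draw (asserted in the tests).
* Thin strata (fewer than two patients in a base year) fall back to growth
  and shares pooled over expense levels of their cell, then to the whole
  cell, then to the global pool, each fallback logged.
* Standard deviations in the result tables are population SDs (the
  published definition is unstated; this is a documented choice).
* Expense growth summary is a compound annual growth rate
  `((last/first)^{1/(n−1)} − 1) × 100`.

## Problem sizes

The default test suite simulates the full published population scale for
single years (≈25,000 patients) and 1/100 to 1/500 scale for multi-year
end-to-end runs; the recovery suite uses 50,000 person-years. The
acceptance script runs the full scale for all nine forecast years (≈230,000
patient-years) plus 100,000 Monte-Carlo draws of the cost rule; it
completes in a few seconds on one CPU.

## Known limitations

* No behavioural response: consumption is identical under every payment
  scheme, so scheme comparisons isolate pure transfer effects.
* Only gender × age band × expense level heterogeneity; no diagnoses,
  providers, geography, or within-year episodes.
* Patients are anonymous annual draws, not linked across years; multi-year
  ceilings or persistence of serious illness cannot be represented.
* The published aggregate tables used as scenario anchors are internally
  inconsistent in places (per-capita costs vs stratum means; a 0.01
  rounding drift in two component rows; a per-capita self-payment column
  whose accounting cannot be recovered); the package reproduces the
  identities that do hold and reports everything else as computed.
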
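# Methods

## Model structure

The model is a deterministic state-transition (Markov) cohort model with a
1-month cycle and a 60-month horizon. Each strategy has at most four live
compartments — *on treatment*, *dropped out* (semaglutide only, stratified
internally by dropout month so each sub-cohort carries its own BMI),
*post-repeat-ESG* (ESG only), and *dead*. The no-treatment cohort occupies
a single natural-history compartment. Within each cycle the engine applies,
in order: (1) mortality, (2) semaglutide dropout, (3) the repeat-ESG flow,
(4) the per-compartment BMI update. Occupancy is conserved to 1e-12 at
every cycle (tested).

BMI is the model's single clinical state variable. Slopes (BMI units per
month): ESG −0.40 (year 1) / +0.0065 (after); semaglutide −0.34 / +0.0012;
dropouts 0 for a 3-month plateau then +0.138; natural history +0.0127.
Re-treated ESG patients receive the year-1 slope for the 12 cycles after
the repeat procedure, then the maintenance slope.

### Conventions chosen where the design was genuinely open

These conventions were selected so that the engine reproduces the published
base-case table from the published inputs; each is a documented, testable
choice rather than a free parameter:

- **Reward accrual.** State rewards (utility, drug cost, complication
  expected flows) accrue on end-of-cycle membership and BMI **from cycle 2
  onward**; the initial-state reward is zero, as in common Markov
  cycle-tree implementations. One-time procedure costs and the 1-week
  procedure disutility attach to their transition cycle (cycle 1, and the
  repeat cycle). There is no half-cycle correction. Under any convention
  that accrues twelve utility-months from cycle 1, a first-year QALY below
  0.776 (= 0.79 discounted) is arithmetically impossible; the published
  first-year values (~0.72) require this lagged-accrual convention.
- **Repeat ESG at cycle 24.** The published cumulative-cost step appears
  inside months 13–24 while the BMI effect appears between months 24 and
  36; both are consistent only with the repeat procedure executed at the
  month-24 cycle (16% of the surviving on-treatment cohort), with the
  year-1 slope applied over cycles 25–36 and complication flows over the
  same window. `repeat_esg_month` is configurable.
- **Uncapped dropout regain.** Dropouts regain +0.138/month for the whole
  remaining horizon. Early dropouts therefore overshoot the natural-history
  trajectory (a month-6 dropout ends near BMI 42 at month 60); an optional
  `dropout_regain_cap` flag clips the regain at the contemporaneous
  natural-history BMI. The uncapped default reflects a constant tracker
  slope and produces the published semaglutide QALY ordering; the capped
  variant raises the semaglutide arm by ~0.01 QALY.
- **Symmetric utility slope.** `u = 0.79 + 0.0056·(37 − BMI)`, clamped to
  [0, 1]: BMI above baseline decrements utility. Transient decrements are
  duration-weighted with 1 month = 365.25/12 days (so 1 week = 0.23 month).
- **Discounting.** `(1.03)^(−(t−1)/12)` per cycle t; cycle 1 undiscounted.
- **Mortality ordering.** Mortality is applied before intra-cycle flows;
  the dead accrue nothing in their death cycle. The 30-day ESG procedural
  mortality (0.2%) combines with background mortality on the survival scale
  in the procedure cycle, and is applied to the repeat procedure as well
  (both behaviours arise from the same code path; setting
  `esg_mortality_30d` to 0 removes both).
- **Headline BMI.** The report's BMI column is the mean among patients
  remaining on their assigned strategy (including post-repeat ESG); the
  cohort-wide alive mean, which drifts upward as semaglutide dropouts
  regain, is available in every trace (`mean_bmi`).

## Parameters

The registry (see `params.default_parameters`) holds every input with base
value, (low, high) range, units, and PSA family. Key values: costs in 2022
USD (ESG $16 360; semaglutide $13 618/yr, accrued monthly while on
treatment; complications $2676/$32 840), class II obesity utility 0.79,
utility slope 0.0056 per BMI unit, decrements −0.22 (1 wk), −0.11/−0.36
(2 wk), discount 3%/yr, WTP $100 000/QALY, cohort age 45 / BMI 37, horizon
60 months, 74% female. Entries printed without a range (the 0.79 utility,
structural constants) are fixed in the PSA unless a configuration supplies
a range. Annual probabilities convert to monthly via
`1 − (1 − p)^(1/12)`; the published years-2–5 semaglutide slope range is
printed reversed and is normalised to (min, max).

## Mortality inputs

Neither the background life table nor the BMI hazard ratios are printed in
the source, so both are synthesized and configurable:

- **Life table.** Gompertz–Makeham hazards per sex
  (µ(x) = λ + a·e^{0.085x}), calibrated to round US-2020 magnitudes
  (q45 ≈ 0.0031 female / 0.0054 male), realized as annual qx for ages
  20–110 and bundled as a CSV fixture with a SHA-256 checksum. It is a
  synthetic stand-in, deliberately not the actual national table. The
  engine blends female/male qx at the cohort's sex mix (default 74%
  female) and looks qx up by completed integer age.
- **BMI hazard ratios.** Piecewise by band, literature-magnitude defaults
  {<25: 1.0, 25–30: 1.2, 30–35: 1.6, 35–40: 2.0, ≥40: 2.6}, multiplying
  the annual probability (capped at 1) before monthly conversion. Over a
  5-year horizon at age 45 this mortality layer moves QALY totals at the
  second decimal, which is why the reproduction checks carry ±0.05-QALY
  tolerances.

## Probabilistic sensitivity analysis

Ranges are interpreted as central 95% intervals: SD = (high − low)/3.92.
Normal distributions are fitted to weight-change slopes, gamma (by moments,
on the cost scale) to costs, beta (by moments, on the probability scale;
decrements on magnitude with the sign restored) to everything else; a
degenerate range collapses to a point mass, and infeasible beta moments
raise an error. Each of the 10 000 iterations draws all ranged parameters
independently, evaluates ESG and semaglutide on the same draw, and records
cost/QALY pairs at 12/24/36/48/60 months; cost-effectiveness is judged by
maximum NMB (ties broken toward the cheaper strategy), which avoids the
sign pathologies of negative ICERs. Runs are bit-reproducible under a
seed. The head-to-head ESG-vs-semaglutide framing mirrors the published
analysis; note that at λ = $100 000/QALY the no-treatment arm has the
highest NMB of all three (its QALY deficit is worth less than the
treatment costs), so acceptability is only meaningful within the active
pair.

Threshold (price) searches solve `inc_NMB = 0` for the target parameter by
Brent bisection (default tolerance $1), re-running the full model at each
evaluation; when the QALY difference is adverse throughout, the solution is
reported on the cost-parity/dominance boundary and labelled as such.

## Synthetic data and the microsimulation oracle

The `synth` module generates everything the analysis assumes but no source
prints: the life table above, perturbed parameter scenarios (PSA draws used
as test fixtures), and an individual-level microsimulation that replays the
cohort model with Bernoulli transitions (death, dropout, repeat selection,
complications) at the same monthly probabilities and slopes, with common
random numbers across strategies. Because utility is linear in BMI over the
realized range, the cohort engine equals the microsimulation expectation;
the suite verifies agreement within 3 Monte-Carlo standard errors at
n = 20 000 for BMI, discounted cost, and discounted QALYs at months
12/36/60. The microsimulation emulates no individual-level heterogeneity in
slopes or utilities — real cohorts vary in treatment response — so passing
these checks validates the engine's expectation arithmetic, not the model's
clinical fidelity.

## Problem sizes

The deterministic base case is 60 cycles × 3 strategies (milliseconds).
The PSA default is 10 000 iterations (~1 minute single-core); the
microsimulation oracle uses 20 000 individuals. These sizes give
Monte-Carlo standard errors well below the decision margins involved.

## Known limitations

- The QALY difference between the active arms computes to ≈ 0.026 at five
  years from the published inputs, roughly half the ≈ 0.056 implied jointly
  by the published QALY totals and the published $3591 semaglutide
  threshold price. No physically sensible dropout trajectory closes that
  gap (it would require dropouts ~10 BMI units heavier than +0.138/month
  can produce), so the threshold search here lands near $4.4k rather than
  $3.6k; all BMI endpoints, QALY totals, costs, and PSA acceptability
  otherwise reproduce the published values within their tolerances.
- Comorbidity resolution, obesity-attributable healthcare costs, treatment
  switching, dose titration, and cause-specific mortality are out of scope.
- Costs are consumed as 2022 USD; no inflation machinery.
- The bundled life table and hazard ratios are synthetic/configurable;
  conclusions about absolute QALY levels inherit their uncertainty.
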
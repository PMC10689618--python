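# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, what the synthetic generators do and do not emulate, and the
design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Plate normalization and toxicity

Each well carries two integrated fluorescence intensities: pHrodo red
(engulfed, acidified synaptosomes — the phagocytosis signal) and calcein AM
green (live-cell mass — the viability signal). Per plate:

- a data well is **toxic** iff its green intensity is strictly below
  `(1 − toxicity_fraction) × median(green over the plate's data wells)`,
  with `toxicity_fraction = 0.30`;
- the per-well ratio `rg = red/green` is expressed as
  `pct = 100 × rg / median(rg over non-toxic data wells)`.

Design choices where the procedure is under-specified:

- **Normalization reference.** The default reference is the data-well
  median; normalizing to the high-control (untreated) wells is available via
  `normalize_to="high_control"`. On a mostly-inactive screen the two are
  nearly identical; the flag exists because both conventions appear in
  practice.
- **Toxic wells are excluded from the ratio median** (their collapsed green
  channel would distort it). Whether the original procedure excluded them is
  unstated; on a screen with a few percent toxic wells the effect on the
  median is negligible.
- Median of an even count is the mean of the two central values; zero-green
  wells are flagged toxic, their ratio is reported as missing, and they
  never enter a median (division guard consistent with "no live cells").
- Invariants enforced by tests: per-plate scale invariance (multiplying all
  intensities by c > 0 changes nothing), exact median-centering at 100, and
  well-order independence.

## Hit calling

Only doses strictly above the 5 µM gate are evaluated, so of the ladder
{1.39, 2.78, 5.56, 11.11, 22.22} µM the top three qualify. If any
qualifying well is toxic the compound is **toxic** (toxicity precedence — a
collapsing well also collapses the ratio, so a directional call there would
be artefactual; the suppressed direction is preserved via the conflict
flag). Otherwise `pct < 70` at a qualifying dose ≤ 20 µM calls
**decrease**, `pct > 130` **increase**; crossings confined to 22.22 µM fall
in the `_gt20` sub-categories, and everything else (the band [70, 130]) is
**no_effect** — a literal "at 100%" rule would classify almost nothing, so
the band between the two published cut-offs defines no-effect. One crossing
dose suffices (the screen is singlicate; no replication requirement exists),
and `supporting_doses` preserves the evidence for stricter downstream
filters. If both directions cross, the direction of the highest qualifying
dose wins and `conflict` is set.

## Dose–response fitting

`fit_dose_response` fits the four-parameter logistic
`y(c) = bottom + (top − bottom)/(1 + (c/EC50)^h)` by least squares on a
log-dose scale, multi-starting over both slope signs and several EC50
guesses, with EC50 bounded to `[min_dose/100, max_dose × 100]`. Optimizer
failure returns `converged=False` instead of raising.

A free 4PL on five singlicate points is weakly identified: when the far
plateau lies outside the dosed range, (bottom, EC50, slope) trade off along
a nearly flat sum-of-squares valley, so small multiplicative noise can move
the EC50 severalfold while barely changing the residual. Two constraints,
both justified by how the data are produced, restore identifiability and
are available as options:

- `baseline=100` anchors the zero-dose asymptote — percent-of-median
  responses are 100 at zero dose *by construction*;
- `fix_slope=1` pins the Hill slope (the standard-slope fit);
- `loss="log"` minimizes log-response residuals, matching multiplicative
  (lognormal) intensity noise.

The EC50 recovery experiment (`experiments.ec50_recovery`) generates
standard-slope curves falling from 100% to 40% with EC50 drawn
log-uniformly on [1, 20] µM — log-uniform being the natural prior for a
concentration-scale parameter — fits noise-free curves with the free 4PL
and noisy curves with the anchored standard-slope configuration, and
reports the worst noise-free relative error and the two-fold recovery rate
at 5% CV noise.

Time-course AUC (`timecourse_auc`) is the trapezoidal area under the hourly
signal, reported as a percent of the vehicle series on the same time grid.

## Network meta-analysis

Inputs are tables: per-drug network gene sets, gene→phenotype annotations,
a phenotype→cluster map, and per-drug effect groups. Presence matrices are
plain set intersections. Open choices:

- **Clustering**: Jaccard distance with average linkage by default —
  the natural metric for sparse binary set profiles (Euclidean/Ward
  available by argument). Two all-zero profiles are at distance 0 by
  convention. Leaf order is scipy's deterministic ordering, so outputs are
  stable.
- **Gene ranking**: one-vs-rest L2 logistic regression (lbfgs, tol 1e-10,
  C = 1, unpenalized intercept), one binary fit per group, genes ordered by
  descending coefficient with lexicographic tie-break. Regularization
  strength and solver are echoed into the output's metadata because ranked
  coefficients are only comparable under a fixed configuration; `C=inf`
  gives the unregularized fit. Groups with fewer than two members are
  skipped with a warning.

## Enrichment

Counts follow the GO-tool convention: background size `N`, term genes in
background `B`, target size `n`, term genes in target `b`. Fold enrichment
`(b/n)/(B/N)` is computed as an exact rational (rounding only at display);
the tail probability `P(X ≥ b)` comes from the hypergeometric survival
function (`b = 0` returns exactly 1). BH q-values use the step-up rule
`q_(i) = min_{j≥i} m·p_(j)/j` capped at 1.

The multiplicity `m` is the supplied term list only — by default terms with
`b ≥ 1` (`fdr_universe="all"` adds tested zero-overlap terms). **q-values
therefore match a published table only when the same term universe is
supplied**; a genome-wide ontology's multiple-testing burden cannot be
reconstructed from a subset of rows.

## Cohort study

All dates are fractional ages in years; calendar time is not modeled.
Cohort rules: **target** = at least one exposure-concept record at an age in
the *closed* interval [6, 18] and a disease diagnosis at age strictly
greater than 18; **comparator** = the adult diagnosis without the pediatric
exposure; index = first qualifying adult diagnosis. The outcome is the
first inpatient visit after index with a disease diagnosis dated within
[visit, visit + 3 days] (billing lag); otherwise censoring at the end of
observation. Rows with non-positive time-at-risk are dropped and counted.

- **Propensity**: L2 logistic regression of exposure on covariates, scores
  clipped to (1e-6, 1 − 1e-6), AUC via the rank statistic.
- **IPW**: stabilized ATE weights (`P(z)/e` for exposed,
  `(1−P(z))/(1−e)` otherwise), truncated at the 99th percentile. ATE is the
  default estimand (weighting by representation in the study population);
  ATT is available.
- **Matching**: greedy variable-ratio nearest-neighbor matching on the
  logit score, caliper `caliper_sd × SD(logit score)`, without replacement,
  up to 20 comparators per target. Comparators are allocated in
  *round-robin rounds* (every target receives its nearest free in-caliper
  comparator before any target receives a second) because a per-target
  grab-all pass exhausts scarce high-score comparators on the first few
  targets. Matched sets carry the standard 1/ratio comparator weights, and
  the matched analysis (Cox and balance) uses them: a pooled variable-ratio
  sample is imbalanced without set weighting. When a dominant binary
  confounder inflates the logit SD, the 0.2-SD default caliper admits
  one-sided within-caliper gaps on the remaining covariates; the bundled
  de-confounding experiment therefore runs with `caliper_sd = 0.05`.
- **Cox fitter**: weighted Breslow partial likelihood maximized by
  Newton–Raphson (gradient norm < 1e-8, step-halving far from the optimum,
  100-iteration cap with a trace on failure). Breslow tie handling is the
  default because the brute-force grid oracle is simple and exact under it.
  The variance is the inverse information for unit weights and the robust
  (sandwich, score-residual) estimator otherwise. No events in one arm is a
  monotone likelihood and raises rather than returning an infinite
  estimate. Balance is reported as standardized mean differences,
  `(mean_T − mean_C)/pooled SD`, with weighted means/variances after
  adjustment; constant covariates report 0.
- Not implemented (out of scope of the emulation): negative-control outcome
  calibration, time-varying exposure, competing risks.

## Synthetic data: what it emulates, and what it does not

- **Plate screen** (`gen_screen`): 384-well plates — rows A–D untreated
  high controls, row E a strong-decrease positive control (the original
  screen's positive-control compound is redacted in the source, so an
  arbitrary strong decreaser stands in; this choice is unverifiable),
  columns 23–24 cell-free low controls, 242 data wells. Each compound
  occupies five data wells (singlicate ladder). Planted classes are
  assigned *deterministically by count* — a seeded shuffle, then the first
  ⌊f·n⌋ ids per class — so recovery tests are exact rather than binomially
  slack. Defaults: 3,280 compounds, 5% increase at 140% of plate median, 5%
  decrease at 50%, 2% toxic (green and red both halved above the gate: dead
  cells neither fluoresce nor phagocytose, which exercises toxicity
  precedence), 5% multiplicative mean-one lognormal noise applied
  independently to both channels (intensities are positive and
  heteroskedastic). Planted effects switch on as a step above the 5 µM
  gate; real dose–response is graded, so threshold behavior near the cut is
  cleaner here than in reality.
- **Time courses** (`gen_timecourses`): saturating accumulation
  `plateau(dose) × (1 − e^{−t/τ})` with τ = 8 h and a 4PL plateau; vehicle
  is dose 0. No photobleaching, well drift, or biphasic low-dose effects.
- **Network tables** (`gen_network_tables`): defaults mirror the published
  scale (239 drugs split 52/43/144 across increase/decrease/no-effect, a
  1,947-gene universe, 77 phenotypes in 10 clusters). Each drug's network
  is 30 uniformly sampled background genes plus planted genes at per-group
  presence probabilities (0.9 in-group vs 0.1 elsewhere by default). Real
  networks are correlated through shared targets and pathway structure;
  these are independent draws, so clustering structure is weaker than in
  real data.
- **Patients** (`gen_patient_table` / `simulate_survival_rows`): exposure
  assigned by a logistic model on baseline covariates (defaults: an
  asthma-like Bernoulli(0.3) with log-odds +2.5 on exposure and log-hazard
  +0.7 on outcome, a N(0,1) utilization score at +0.5/+0.2, intercept −2 —
  roughly 27% exposed), event times exponential with hazard
  `0.04 × exp(log(HR_true)·z + β'x)` per year, true HR 0.75, administrative
  censoring 15 years after an index age drawn uniform on [19, 30], n =
  20,000. The confounder strengths are fixed study conditions chosen to
  produce a clearly confounded crude estimate; hazards are
  time-constant, so proportional hazards holds exactly — real EHR data
  would add informative censoring, enrollment gaps and vocabulary noise
  that the emulation does not model. The Cox-recovery experiment uses the
  unconfounded variant (fair-coin exposure, baseline 0.06/yr, 10-year
  horizon, ~40% events).

Passing tests on these generators demonstrate that the *computational
pipeline* is correct under its stated model; they do not validate the
biology or the robustness of any step to real-data pathologies the
generators exclude.

## Problem sizes

The bundled experiments run at the sizes reported by
`scripts/acceptance.py`: the full 3,280-compound screen (twice: noisy and
noise-free), 200 dose–response curves per noise level, 100 Cox replicates
at n = 20,000, 10 confounded cohorts at n = 20,000, 20 network simulations
at 300 drugs over a 500-gene universe, and the complete enumeration of
hypergeometric configurations up to N = 12.
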
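# Methods

`frailspan` re-implements, as a tested pipeline, the analysis workflow of a
longitudinal frailty ("Fragility Index") aging study in mice: weekly clinical
phenotyping from mid-life to natural death, terminal-decline prediction, and
lifespan/healthspan survival comparison.  Because raw data from such studies
are not publicly deposited, every stage is driven by a synthetic cohort
generator whose defaults emulate the study design; this note records the
models, the parameters that matter, and the limits of what the synthetic
cohorts can show.

## Fragility Index scoring

The FgI is the mean deficit level over a 30-item ordinal catalog.  Most items
are scored {0, 0.5, 1} (absent / mild / severe); a configurable subset is
binary {0, 1}.  Dermatitis arrives on a 4-level clinical scale and is
collapsed 0→0, 1→0.5, 2→0.5, 3→1; any monotone surjection onto the 3-level
scale would be admissible, and the collapse is exposed for substitution.
Missing items are dropped from the mean's denominator (no imputation), so an
assessment with zero observed items has an undefined score.  "Severe" means
a score of exactly 1, the maximum for both 2- and 3-level items.  Which items
are binary is not fixed by any data standard; the default marks six
presence/absence conditions (paralysis, rectal prolapse, malocclusions,
diarrhea, nasal discharge, vaginal/uterine prolapse) and is configuration.

## Synthetic cohort generator

Two arms mirror the study design: inbred C57BL/6J (B6) of both sexes enrolled
at 730 days on an ad-libitum diet, and Diversity Outbred (DO) females
enrolled at 913 days across five diet groups (AL, IF1, IF2, CR20, CR40),
assessed weekly until death.

**Lifespans.** Gompertz hazard h(t) = a·exp(b·t) per strain with a
proportional per-diet multiplier exp(logHR), left-truncated at the enrollment
age by exact inverse-CDF conditional sampling.  Defaults (B6: a = 3.2e-5,
b = 0.006/day; DO: a = 9.6e-5, b = 0.004/day; diet logHRs 0 to −1.3) were
solved from the published cohort medians — roughly 29 months for B6 and 37
months for DO conditional on enrollment — so generated summaries land in a
realistic range.

**Terminal decline.** Each mouse gets a decline onset in proportion-of-life-
lived (PLL) units, drawn around the population onset (default 0.95) with SD
0.012; decline follows a logistic ramp in PLL with steepness k = 120 (a
transition over roughly the last two weeks of life, matching the timescale
the TxW rule was designed for).  Body weight and temperature drop by a
per-mouse lognormal multiple (CV 0.5) of the configured magnitudes (20% of
baseline weight, 2.5 °C) times the ramp, plus weekly measurement noise
(1 g, 0.4 °C).  The onset heterogeneity and drop variability are what keep
the TxW criterion imperfect — sudden deaths yield false negatives, early
decliners false positives — as observed for that rule in real cohorts.

**Deficit dynamics.** Each item follows an ordered-logit observation model
with linear predictor slope·clock + ramp_coef·ramp(PLL), combined with an
accumulation process: at each weekly visit a candidate score is drawn and the
state ratchets upward (max of state and candidate); a non-severe state remits
with probability 0.15; severe is absorbing.  Because scores ratchet, the
per-visit ordered-logit probabilities act as discrete-time hazards, and the
default thresholds are placed so that *cumulative* incidence is realistic:
FgI scores span roughly [0.02, 0.57], the median per-mouse maximum severe
count is ~8, and ~95% of mice accumulate 4+ severe deficits before death.
Items fall in three tiers: eight "terminal" items whose odds spike with the
ramp (breathing rate/depth, tumors, body condition, tremor, pallor/cyanosis,
dehydration, tail stiffening, head piloerection), a background of gradually
accumulating items with no terminal component, and two never-observed items
(nasal discharge, vaginal/uterine prolapse) that exercise the zero-variance
filter.  This tiering is a modeling choice — no quantitative per-item
trajectory model exists to copy — and it reproduces the qualitative feature
that a minority of items track imminent death while the summary score
dilutes them.

The accumulation clock is configurable: `deficit_clock="pll"` (default) ties
accumulation to relative lifespan; `"age"` ties it to chronological age
(normalized by 1100 days), which decouples frailty accumulation from lifespan
and is the configuration used to demonstrate lifespan/healthspan
dissociation.  Two items (head piloerection, thoracic mass) default to a
study start-day of 14, emulating assays added after study start; visits are
skipped completely at random at rate 0.02 and items masked at rate 0.002.
A 365-day unrecorded burn-in lets mice carry accumulated deficits at
enrollment.

**What the generator does not emulate.** Specific pathologies and causes of
death, technician and seasonal effects, staggered enrollment, informative
missingness, and any correlation structure among items beyond the shared
ramp.  Passing tests therefore show that the *pipeline* recovers what the
generator plants, not that the models would achieve the same performance on
real colony data — on real data every predictor is substantially weaker.

## TxW terminal-decline rule

TxW = temperature × weight.  At each visit the mean TxW over the recent
window (last 21 days, inclusive of the visit) is compared with a benchmark
window 63–91 days before; a change of −10% or worse flags terminal decline.
Day-based windows (half-open on the left, closed on the right), a minimum of
2 observations per window, and the inclusive −10% boundary are pinned
conventions, config-exposed via `TxwParams`; the original rule's week-based
bookkeeping is ambiguous about skipped visits, and day arithmetic is not.
Validation against the 95PLL label (PLL > 0.95, strict) reports PPV and NPV
per stratum with `insufficient` rows excluded.

## Endpoints and lifespan statistics

PLL = age / lifespan; the 95PLL event is strict (PLL > 0.95); life
expectancy = lifespan − age.  All quantiles (median, IQR, 90th percentile
"maximum lifespan") use linear interpolation, one convention everywhere.
The quantile test of proportions thresholds at the pooled q-th quantile and
tests the per-group counts above it by chi-square without continuity
correction (Fisher's exact for sparse 2×2 tables); the variance comparison
is Brown–Forsythe (ANOVA on absolute deviations from group medians).  Both
are calibrated to nominal type-I error in the acceptance suite.
Life-expectancy correlations are Pearson with Fisher-z 95% CIs, computed per
item plus FgI score, severe-deficit count, age, weight, and temperature;
zero-variance items are reported blank.  Repeated measures are pooled as
independent observations (the convention of the tabulations this mirrors); a
clustered alternative would shrink the CIs' nominal validity claims, not the
point estimates.

Trajectories on the PLL scale are smoothed by lowess on a fixed grid (step
0.005).  The inflection estimate is the grid point maximizing the second
difference of the smoothed curve on PLL ∈ [0.6, 1.0], reported as "none"
when maximal curvature is below 1e-4 of the curve's range (straight lines).
For dense weekly cohorts the span is 0.08: larger spans smear the curvature
peak leftward by about half the bandwidth, which is the dominant bias of
this estimator.

## Mixed-effects 95PLL models

Risk of 95PLL is modeled per strain by logistic regression with fixed
effects (TxW flag alone, or TxW flag + FgI score on its natural [0, 1]
scale) and a Gaussian random intercept per mouse.  Fitting is maximum
likelihood with 25-node Gauss–Hermite quadrature over the one-dimensional
random effect — agreeing with `lme4::glmer(nAGQ=25)` to three decimals in
the test suite — with Wald intervals from a finite-difference Hessian.
Predictions for unseen mice use the fixed effects only (random intercept 0).
Rows with insufficient TxW history are dropped from fitting and evaluation,
since the rule needs a 13-week look-back.

## Stacked ensemble

Feature recipes are nested: M0 = age + diet (+ sex/strain indicators when
they vary); M1 adds current weight/temperature and their 30-day rolling
percent change (current vs the earliest observation in the preceding 30-day
date window); M2 adds the 30 deficit items rescaled to integers with equal
absent-to-severe distance ({0,1}→{1,3}, {0,0.5,1}→{1,2,3}), zero-variance
filtered and reduced to 5 principal components; M3 adds 30-day item deltas,
reduced to 5 further components.  PCA loadings are sign-pinned (largest
element positive) for reproducibility; all scaling/rotation constants are
learned on training rows only.  Mice with under 30 days of observation and
rows missing any required input are excluded.

Mice — never rows — are split 25% to test, stratified by diet with
largest-remainder rounding; training mice get 5 grouped CV folds.  Event
rows are up-sampled to class balance inside each training fold only.  For
each learner (RF, SVM, RLR, XGB) × recipe, up to 25 hyperparameter
configurations are tuned on grouped-CV ROC-AUC with racing-style early
elimination (configs trailing the best running mean by more than a margin
after 3 folds are dropped; survivors finish all folds so the winner has
complete out-of-fold coverage).  Stacking fits a logistic meta-model on the
pooled out-of-fold probabilities with non-negative member weights and an L1
penalty — with the non-negativity constraint the penalty is linear, so
box-constrained L-BFGS-B solves it exactly — choosing the penalty by grouped
CV; members with non-zero weight are refit on all training rows.  Reported
metrics are accuracy/PPV/NPV at thresholds 0.5–0.9 plus ROC-AUC and PR-AUC.

Attribution for the highest-weight member uses an in-package permutation
(interventional) Shapley estimator: features are switched from a background
row's values to the explained row's values in random permutation order and
each feature is credited with the change in predicted probability.  The
telescoping sum makes per-row attributions add exactly to prediction minus
baseline for any number of permutations.

One cross-strain ensemble with strain/diet covariates is the default
(evaluation can be stratified by strain); per-strain ensembles are obtained
by filtering the input.  A master seed expands deterministically
(`numpy.random.SeedSequence`) into split, up-sampling, grid-sampling, and
learner seeds, and member refit seeds are keyed to candidate identity so
duplicated candidates refit identically.

## Healthspan

Healthspan is the length of life lived with fewer than four severe deficits:
the event is the age at the first assessment with `n_severe >= 4` (no
interpolation between weekly visits; a crossing hidden inside a missed week
is not imputed), and mice that die without crossing are censored at death.
The threshold is configurable.  Kaplan–Meier estimation and log-rank tests
come from lifelines; summaries reuse the same quantile conventions, with
censored records excluded from naive quantiles by default.

## Problem sizes and numerical choices

Acceptance-level checks run at desk scale by design: cohorts of 280–300 mice
(weekly rows in the tens of thousands), 10 master seeds for the predictor
ranking with compact hyperparameter grids, 100 replicates for mixed-model
coverage, and 2,000 replicates for each null-calibration check.  Degenerate
inputs are errors, not silent results: single-class outcomes, empty groups,
all-identical values in the quantile test, one-class test sets, and
all-zero stacking weights each raise with an explanation.  Optimizer
tolerances: Nelder–Mead then BFGS polish for the mixed model (log-scale
random-effect SD, clipped to avoid overflow); finite-difference Hessian step
1e-4.

## Known limitations

* Wald intervals undercover when the random-intercept SD is near zero.
* The inflection estimator has a small negative bias (curvature of a smooth
  ramp peaks before its center); with the default steepness this is well
  inside the ±0.02 recovery tolerance, but flatter ramps would push it out.
* Up-sampling duplicates rows rather than reweighting learners; ensemble
  probabilities are not recalibrated afterwards.
* Synthetic cohorts are easier to predict than real ones: the generated
  AUCs are upper bounds of convenience, and only the *ordering* of the three
  predictors is treated as a meaningful result.
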
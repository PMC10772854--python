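# Methods

## Scope

`predvalid` implements internal validation of clinical prediction models
for binary outcomes fitted by maximum-likelihood logistic regression:
performance measurement (discrimination and calibration), four
internal-validation strategies (apparent, random split-sample, k-fold,
enhanced bootstrap with optimism correction), uniform shrinkage,
internal-external cross-validation (IECV) over clusters with
random-effects pooling, subgroup audits, a synthetic-cohort generator with
known ground truth, and a bias/variability experiment harness.
Out of scope: survival outcomes, temporal/geographical recalibration,
decision-analytic measures (net benefit), missing-data handling (input is
complete-case), and penalised or machine-learning model builders.

## Performance measures

For a model with linear predictor ``lp = a + Xb`` and risk ``expit(lp)``:

* **c statistic** — concordance probability over event/non-event pairs,
  ties counted 1/2. Computed from midranks (O(n log n)). The default SE is
  DeLong's placement-variance estimator with a Wald 95% CI clipped to
  [0, 1]; a bootstrap-percentile CI (resampling individuals) is available
  via ``ci_method="bootstrap"``. With a single event or non-event the SE is
  undefined and reported as NaN.
* **calibration slope** — slope of the logistic regression of the outcome
  on ``lp`` (free intercept); ideal 1. Wald SE/CI from the refit.
* **calibration-in-the-large** — intercept of the logistic fit with ``lp``
  as offset; ideal 0. Wald SE/CI. Slope/CITL CIs are not clipped.
* **flexible calibration curve** — default is a local-linear smoother
  (lowess, frac = 0.6, 0 robustness iterations) of the 0/1 outcome on the
  risk scale, evaluated on a 100-point grid spanning the 1st–99th risk
  percentiles; the alternative fits a logistic regression on a 4-knot
  restricted cubic spline of logit(risk) (knots at the 5/35/65/95th
  percentiles). A floor of 50 individuals is enforced — below that a local
  smoother of a binary response is dominated by noise and grouped
  observed/expected proportions are the honest display.

Degenerate inputs raise typed errors: single-class outcomes
(`DegenerateOutcomeError`), constant linear predictors (`DataError`),
separation or IRLS non-convergence (`FittingError`, which carries the
strategy/replicate context so resampling callers can log-and-skip).

## Model building and shrinkage

`ModelBuilder` encapsulates the whole development recipe so that
resampling strategies can repeat it in full — selection included — rather
than merely refitting coefficients. The default recipe fits all candidate
predictors without selection, matching the illustrative trauma-mortality
model that enters 14 predictors (4 clinical + 10 noise) directly. Backward
elimination at a Wald threshold (default alpha = 0.157, the 1-df
AIC-equivalent) is available. Building is a pure function of (data, seed).

Uniform shrinkage multiplies the coefficients by a factor (in practice the
optimism-corrected calibration slope) and re-estimates the intercept as
the MLE of an intercept-only logistic model with the shrunk linear
predictor as offset. The score equation of that fit makes the mean
predicted risk equal the observed event fraction on the development data
(conservation holds to the IRLS tolerance, well below 1e-8); it is the
calibration-in-the-large correction applied after shrinkage.

## Internal-validation strategies

* **Apparent** — build and evaluate on the same data.
* **Split-sample** — one random split with development size
  ``round(dev_fraction · n)`` (optionally stratified by outcome). A side
  with a single outcome class is an error, never a silent re-split:
  re-drawing splits until the test result looks good is result shopping.
* **k-fold** — fold assignment is cyclic over a shuffled, class-ordered
  index, which guarantees simultaneously that folds partition the data,
  that sizes differ by at most 1, and (when stratified, the default) that
  each class is spread across folds within ±1. Defaults k = 10, one
  repeat. Per fold, the full recipe is re-run on the other k−1 folds and
  evaluated on the held-out fold. The headline estimate is the mean of
  per-fold values (median optional); pooling the held-out predictions and
  computing one set of metrics is offered behind ``pooled=True`` because
  the two aggregations differ when folds are small. Leave-one-out is
  rejected whenever k exceeds the minority class count, since a held-out
  fold without both classes has no c statistic.
* **Enhanced bootstrap** — the seven-step optimism correction: apparent
  performance on the full data; then per replicate a bootstrap sample of
  size n with replacement, full rebuild on it, evaluation on the bootstrap
  sample and on the original data, optimism = the difference; averaged over
  B replicates and subtracted from the apparent estimate, per measure. The
  per-replicate optimism table is returned to show stability, and the
  corrected calibration slope is exposed as the shrinkage factor. Default
  B = 500; a few hundred replicates already estimate optimism precisely,
  which is why the experiment harness uses B = 100 inside its replicated
  cells.

Replicate failures (separation in small bootstrap samples or folds) are
skipped and counted; more than 5% failures aborts the run, since silently
retrying or dropping many replicates would bias the correction.

All randomness flows from one caller-supplied master seed through numpy
`SeedSequence` spawning, so every experiment replays bit-for-bit.

## IECV and pooling

`iecv_run` builds the deliverable model on all data, then holds out each
cluster once, re-running the recipe on the remaining clusters and
evaluating in the held-out one. Clusters with a single outcome class are
excluded from the held-out rotation (their c statistic is undefined) with
a warning, but their individuals stay in every development set. At least
three evaluable clusters are required.

Cluster estimates are pooled by DerSimonian–Laird random-effects
meta-analysis: Q from inverse-variance fixed-effect weights,
``tau² = max(0, (Q − df)/C)``, random-effects weights ``1/(se² + tau²)``,
Wald CI. DL was chosen over iterative estimators (REML, Paule–Mandel)
because it is closed-form, standard, and sufficient for the small numbers
of clusters typical of IECV. Pooling is on the natural c scale by default,
matching how pooled c statistics are usually displayed; a logit-scale
option (delta-method SEs, back-transformed CI) is provided for estimates
near 1. `forest_table` exports the per-cluster + pooled rows; rendering a
plot is left to the caller.

Subgroup audits evaluate one fitted model within each level of a labelled
column, with a reporting floor (default 20 individuals and 5 of each
outcome class); groups below the floor are flagged "insufficient data"
rather than dropped.

## Synthetic-cohort generator

The generator is a statistical stand-in for a large trauma-trial cohort,
calibrated to two anchors: event fraction 0.15 and large-sample
c statistic 0.815. It is *not* a reconstruction of any real trial's
marginals or correlations, so numerical agreement with published analyses
of real data is not expected — direction and ordering properties are what
the simulations establish.

Structure: 4 informative predictors (three independent standard normals
and one Bernoulli(0.5) sex-like indicator, all entered linearly) with base
coefficient shape (0.7, 0.4, −0.5, −0.9), plus 10 independent standard
normal noise predictors with true coefficients exactly 0. The outcome is
Bernoulli with logit equal to the true linear predictor.

Calibration is deterministic and independent of the user seed: a fixed
million-draw quadrature sample of the informative predictors is drawn from
an internal seed; the intercept solves the target event fraction on it by
Brent root-finding (so event-fraction calibration does not drift from seed
to seed); the coefficient scale is found by bisection until the
large-sample c is within ±0.002 of target (50-iteration cap). The
large-sample c is computed on the quadrature sample by averaging
analytically over outcome draws — a weighted concordance with weights
``p_i (1 − p_j)`` over ordered pairs, ties on the linear predictor counting
1/2 — which removes outcome-sampling noise from the bisection. Calibrated
truths are memoised per configuration.

The clustered variant draws cluster sizes uniformly in a configurable
range (default matching nine regions of 3066–15 583 individuals; the test
suite scales this by 0.1 for speed) and adds per-cluster intercept offsets
drawn Normal(0, sd); sd = 0 gives the homogeneous benchmark used for
tau² ≈ 0 recovery tests. Offsets perturb the realised event fraction
slightly; that is intended (they model between-centre baseline-risk
heterogeneity).

## Experiment harness

`run_experiment` draws, per (n, replicate) cell, either a fresh generated
cohort (generator mode) or a with-replacement subsample of a supplied
superpopulation, applies each strategy, and emits one tidy record per
measure with the reference value and the difference. The reference
semantics differ by mode and are stamped on every row: generator mode uses
the exact generator truth (and ideal slope 1 / CITL 0); superpopulation
mode uses the apparent performance of the model built on the whole
superpopulation — itself an apparent value, and the two must not be
conflated. Split strategies record the held-out (test) side; the apparent
side of a split is already characterised by the apparent strategy.
`summarize_bias` reports the mean and 2.5/97.5% quantiles of the
difference per (strategy, n, measure) — quantiles rather than SDs because
the summaries describe point clouds at modest replicate counts.

## Problem sizes used in tests and the acceptance script

The test suite runs the ordering experiment at 100 replicates with
n ∈ {200, 1000, 5000} and B = 100; IECV recovery at 100 replicates of nine
clusters sized in [306, 1558]; shrinkage efficacy at 100 replicates of
n_dev = 200 with B = 200 against a fixed n = 100 000 test cohort. The
acceptance script uses 50 experiment replicates, 20 IECV replicates and 30
shrinkage replicates. These sizes give Monte-Carlo error comfortably
smaller than the effects being demonstrated while keeping a full run on a
single CPU in minutes.

## Known limitations

* Predictors are generated independent; real clinical predictors are
  correlated, which changes the magnitude (not the direction) of optimism
  at a given n.
* DeLong CIs are Wald-type and degrade for c very near 1 or tiny event
  counts; the logit-scale pooling option mitigates this at the
  meta-analysis level but per-cluster CIs remain Wald.
* The k-fold aggregation default (mean of per-fold estimates) is not the
  same estimand as pooled-prediction metrics; both are exposed, and the
  difference matters for small folds.
* The bootstrap resamples individuals, ignoring any clustering; a cluster
  bootstrap is not provided.
* Backward elimination uses Wald p-values, not likelihood-ratio tests; at
  the default threshold the two rarely disagree, but they can near the
  boundary.
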
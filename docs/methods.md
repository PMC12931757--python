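# Methods

`mafldpred` re-implements, as a testable pipeline, a clinical
machine-learning workflow for predicting metabolic-associated fatty liver
disease (MAFLD) in type-2-diabetes (T2DM) patients from routine demographic
and laboratory variables.  Because the underlying hospital dataset is not
public, every stage operates on synthetic cohorts whose statistical
structure is calibrated to the published class-conditional descriptives.
This note records the models, the defaults that matter, and what the
synthetic setting does and does not establish.

## The cohort model

The cohort is a rectangular table of 31 predictors — 25 continuous
laboratory/anthropometric variables and 6 binary history variables — plus a
binary MAFLD target.  The generator draws, per record:

* a class label at a configurable prevalence (default 1827/3740, the
  pre-balancing MAFLD share; labels are realized as exact counts and
  shuffled, so class sizes are deterministic);
* one latent standard-normal vector per record with a configurable
  correlation matrix (Gaussian copula).  Default correlation: 0.6 among
  anthropometrics (weight, BMI, waist, hip), 0.5 between ALT and AST, 0.3
  among lipids, 0 elsewhere.  No correlations are published; these defaults
  are deliberately conservative and fully overridable;
* continuous margins from class-conditional **shifted log-normal**
  distributions `X = c + exp(mu + sigma Z)`.  The three parameters are
  solved numerically so the distribution's mean, Q1 and Q3 equal the
  published class-conditional targets.  The skew ratio
  `r = (mean - Q1)/(Q3 - Q1)` pins down `sigma` alone and admits an exact
  solution whenever `r > 1/2` (right skew).  A few published triples imply
  left skew (e.g. age in the MAFLD class: mean 55.3, Q1–Q3 47–64); those
  have no solution in this family, so the margin falls back to matching
  mean and Q3 only at a fixed mild `sigma = 0.3`, and the calibration log
  flags the variable.  The family choice reflects the reported
  non-normality (Shapiro–Wilk) and right skew of lab variables;
* binary margins by thresholding the latent normal at the class rate.

Values are clipped to broad physiologic plausibility ranges (the same
ranges the cleaning stage uses).  The ranges are configuration defaults,
not clinical reference intervals, and are wide enough that clipping does
not measurably bias the calibrated means.

## Missingness model

Six variables — sex, age, height, weight, DBP, BMI — are always complete,
matching exports where demographics and vitals accompany every visit.  The
remaining 25 variables receive missingness at configurable per-column rates
(defaults 5–40%, higher for specialised labs such as insulin/HOMA, CRP and
vitamin D; the true per-column rates are not published).

Two mechanisms are supported:

* **MCAR** — independent Bernoulli per cell at the column rate.
* **MAR** — a per-column logistic model on z-scored always-observed drivers
  (default: slope 2 on age, 1 on BMI), plus a per-record latent "workup
  completeness" effect (sd 1.5) shared across columns.  Exactly
  `round(rate * n)` cells per column are masked by probability-weighted
  sampling without replacement, so realized rates are exact.

The panel effect encodes that labs are ordered together: without it, 25
nearly independent missingness processes leave essentially no fully
observed records, which contradicts any export from which a complete subset
can be extracted.  It is independent of the data values, so the mechanism
remains MAR.  The driver slopes sit in the strong-driver regime because the
emulated study's incomplete data rejected MCAR decisively; at these
defaults Little's test on a 3,740-record cohort rejects as well, while
~18% of records remain fully observed.  Ground truth for every masked cell
is retained for scoring.

## Little's MCAR test

The test estimates the grand mean and covariance of the incomplete table by
EM under a multivariate-normal model (tolerance 1e-6 on the observed-data
log-likelihood, max 500 iterations; the log-likelihood is non-decreasing by
construction and that property is tested).  Records are grouped by
missingness pattern and

    d2 = sum_j n_j (ybar_j - mu_j)' Sigma_j^{-1} (ybar_j - mu_j),
    df = sum_j p_j - p,

with mean and covariance restricted to each pattern's observed variables.
Every pattern contributes regardless of size: the restricted covariance is
the global EM estimate, so singletons are unproblematic (an early design
sketch merged small patterns; that discards nearly all information under
panel missingness and was abandoned).  Binary variables enter as 0/1
numerics — an approximation shared by common implementations and flagged as
such.  Simulation suites check the type-I error (bivariate, n=500, 1,000
replicates, rejection rate in [0.03, 0.07] at alpha 0.05) and power under a
slope-2 MAR mechanism (n=1,000, at least 0.8).

## Learned-MAR amputation

The missingness-replication procedure: split the data into random halves;
extract the fully observed subset of one half; on the other half, take each
incomplete column in turn as a binary target (missing = 1) and tune eight
candidate classifiers (logistic regression, k-NN, SVM, decision tree,
random forest, extra trees, AdaBoost, XGBoost) by grid-search CV, selecting
on mean F1 (robust to the class imbalance of rare missingness); then score
every complete-subset record with each column's chosen model and null the
top `round(rate * n)` records by predicted probability, where `rate` is the
column's observed missingness fraction.

Design points the source leaves open, resolved here:

* all columns' null sets are computed from the *pre-amputation* complete
  values and applied jointly; a sequential mode (earlier nulls visible to
  later predictions, order-dependent) exists behind a flag;
* predictor columns' own missing entries are median/mode-filled while
  training the missingness classifiers;
* boundary ties in the probability ranking break by record id, making plans
  deterministic under a fixed seed;
* hyperparameter grids are compact literature-standard defaults (the
  original grids are unpublished) and overridable.

## Imputation benchmark

Nine methods: chained-equations imputation with ridge, SVR, decision-tree,
random-forest, extra-trees, AdaBoost or gradient-boosted-tree estimators
(sklearn's IterativeImputer: max 10 sweeps, tolerance 1e-3, visiting
variables in ascending missingness), a k-NN imputer, and missForest
(iterative random-forest imputation that stops when the change in imputed
values first increases, returning the previous iterate).  Binary
imputations are rounded to {0,1}; continuous ones are clipped to the schema
ranges; observed cells are asserted unchanged.

Scoring: per variable, R^2 over the amputated cells (SST about the
amputated-cell truth mean) for continuous variables, accuracy for binary;
aggregated with weights equal to each variable's missingness proportion.
The winner is selected on the continuous aggregate — binary accuracies
barely separate the methods — and a mean/mode baseline is scored alongside
but never competes.  The same amputation plan is shared by all methods
within a seed, and the whole loop repeats across five seeds.

Note on interpretation: because amputated cells are the *highest
missingness-probability* records, their truth mean differs from the column
mean, and variables that are conditionally unpredictable under the default
copula (e.g. insulin with no configured correlates) get negative R^2 for
every method.  That is a property of the scoring target, not a defect;
cross-variable signal (waist/hip from weight/BMI) is what separates the
multivariate methods from the baseline, and the benchmark's comparative
ordering is what the pipeline consumes.

## Preprocessing

Cleaning order: range filter (out-of-range cells become missing, closed
intervals), feature drop (missing fraction strictly > 45%), row drop
(strictly > 50% over surviving features), exact-duplicate removal (first
kept).  The sensitivity analysis reruns cleaning at 30/45/60% and compares
surviving cohorts pairwise by standardized mean difference and two-sample
Kolmogorov–Smirnov p per variable.  Outliers: local outlier factor on
standardized continuous features after imputation (k = 20, flag at score
> 1.5 by default; both data-dependent, neither published).  Balancing:
random undersampling of the majority class by default; SMOTE (convex
interpolation between minority neighbours, binary features by
nearest-endpoint rounding) as the comparison variant.

## Modeling

Stratified 80/20 split; all development on the training 80%.  Per
classifier (logistic regression, k-NN, SVM, decision tree, extra trees,
gradient boosting, XGBoost, LightGBM): exhaustive grid search by stratified
5-fold mean accuracy (ties break by grid order), then feature selection
fitted on the training set only:

* **SelectKBest** — ANOVA F for continuous and mutual information for
  binary features.  The two scores are not on a common scale, so features
  are merged on within-family percentile ranks; k is tuned by CV accuracy
  of the wrapped classifier.
* **PCA** — standardized components, count tuned the same way, capped at
  the feature count.
* **RFECV** — one-at-a-time elimination by coefficient magnitude or
  impurity importance (a standardized-logistic surrogate ranks for models
  exposing neither, e.g. k-NN); the subset size with the best wrapped-
  classifier CV accuracy wins.
* **GA** — binary masks, CV-accuracy fitness (cached per mask), tournament
  selection (size 3), uniform crossover, bit-flip mutation, elitism 1,
  early stop after 10 stagnant generations; empty masks are repaired.  The
  GA's population size, crossover rate and mutation rate are chosen by a
  Taguchi L9 orthogonal array: each of the nine rows runs once and the best
  row's result is adopted (no tenth run).

Metrics per fold: accuracy, precision, recall, F1 at threshold 0.5, and
threshold-free AUC.  The whole CV is repeated across seeds, and two
aggregation axes are reported — the t-based 95% CI across the pooled folds
and across the per-repeat means — because the source is ambiguous about
which axis its intervals use.  Feature importances (impurity-based or
|coefficient|) are normalized per model; the importance table averages the
three best models by CV accuracy, excluding models without importances.

## Problem sizes

Defaults in the analysis drivers: cohort n = 3,740 (the pre-balancing
size); benchmark across 5 seeds with 3-fold tuning and compact grids; the
model grid runs 5 CV repeats.  The test suite uses smaller cohorts
(hundreds to a few thousand records) and single-configuration grids, sizes
chosen so each statistical check retains the power its assertion needs.

## What passing tests do and do not show

The synthetic cohort reproduces the published class-conditional margins,
the always-complete column structure, an MCAR-rejecting MAR mechanism, and
exact realized missingness rates.  It does not reproduce: the real
correlation structure (unpublished; the default copula is sparse), the true
per-column missingness rates, measurement error, or any site-specific
artefacts.  Consequently the pipeline's *procedures* — amputation-rate
exactness, scoring closed forms, selection/evaluation hygiene, GA
optimality, statistical calibration of Little's test — are verified, while
the published headline performance numbers (test accuracy 0.806, AUC
0.889, the per-column imputer winners, the 29 LOF outliers) are
data-dependent and are treated as directional context only; the synthetic
cohort happens to land in the same performance neighbourhood, but nothing
is calibrated to make it do so.

## Known limitations

* Continuous margins are unimodal shifted log-normals; variables that are
  mixtures (e.g. insulin under treatment) are only coarsely emulated.
* Deterministic identities between variables (BMI = weight/height^2,
  HOMA = FBS x insulin / 405) are not enforced; each margin is calibrated
  independently.
* Little's test treats binary 0/1 columns as normal; with very rare events
  (CVA at ~1%) the chi-square approximation is rough.
* The GA's fitness caching assumes a deterministic CV split per seed;
  changing fold seeds between evaluations would invalidate the cache.
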
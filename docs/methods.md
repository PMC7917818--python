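# Methods

`koaprog` implements a machine-learning pipeline for predicting structural
progression of knee osteoarthritis (KOA) from a baseline feature table.
Radiographic progression is measured by medial joint-space-narrowing (JSM)
grades, an ordinal 0–3 score recorded per knee at each follow-up visit.
The pipeline has five stages — pre-processing, progression phenotyping by
clustering, ensemble feature selection, incremental model selection, and
Shapley-value explanation — plus a synthetic cohort generator that makes
every stage testable without access-restricted registry data.

## Progression statistic and phenotype labeling

For a knee with grades m_1 … m_n over n visits (default n = 5), the
progression statistic is the sum of absolute consecutive differences,

    s = Σ_{k=2..n} | m_k − m_{k−1} |,

and the combined-knees statistic is s_left + s_right.  s = 0 iff the
trajectory is constant, and s is invariant under reversing the visit
order.  Subjects with any missing visit are excluded rather than imputed:
filling in an ordinal grade would fabricate progression.

Subjects are clustered on this one-dimensional statistic with either
k-means or k-medoids under city-block (L1) distance with 5 replicates, or
agglomerative (complete-linkage, Chebyshev-distance) hierarchical
clustering.  The L1 k-means updates each center as the per-cluster median;
k-medoids restricts centers to data points (the lower median).  Each
replicate runs Lloyd iterations from a random pair of distinct score
values and then applies a boundary-refinement pass: in one dimension the
optimal L1 partition is contiguous in sorted order, so blocks of equal
values are moved across adjacent cluster boundaries while the total
within-cluster cost decreases.  This matters in practice — progression
scores have a large point mass at 0 and a handful of small integer values,
a geometry in which plain Lloyd iterations frequently stall in partitions
that cut at 1 instead of 0.  With refinement the replicates attain the
brute-force-optimal two-partition objective on every small-set battery we
test.

The number of clusters is chosen by the Davies-Bouldin index (mean
centroids, Euclidean distances, scan k = 2…6; ties to the smaller k), with
a `force_k` override; the adopted setting for labeling is k = 2, the
standard choice for a binary progressor phenotype.  On integer-valued score
distributions the DB index rewards putting each small integer in its own
cluster (near-zero scatter), so an automatic scan often prefers k > 2
there; the index behaves as intended on continuous, well-separated score
samples.  A k in the scan whose index is undefined on the data (coincident
centroids) is recorded as NaN and skipped.

The two-cluster solution is binarized — the lower-mean cluster is the
non-progressor class 0 — and the majority class is undersampled uniformly
at random to the minority size.

## Pre-processing

Order is fixed: (1) drop columns whose missing fraction strictly exceeds
20 % (a column at exactly 20 % survives); (2) impute remaining missing
cells with the column mode, ties broken by the smallest value so the step
is deterministic; (3) min-max normalize every column to [0, 1], constant
columns mapping to zero.  All statistics are estimated on training rows
only; held-out rows are transformed with the stored parameters and clipped
to [0, 1] (values can fall outside the training range, and refitting on
test rows would leak).  Column kind (numeric vs. integer-coded
categorical) always comes from the declared schema, never from the values.

## Ensemble feature selection

Six scorers each nominate a top-K subset (default K = 200, so downstream
accuracy curves can extend well past the feature counts where models
typically peak):

* **pearson** — |point-biserial correlation| with the class; constant
  features score 0.
* **chi2** — chi-squared statistic of per-class feature sums against their
  class-proportional expectation (valid because normalization makes all
  values non-negative).
* **rfe** — recursive feature elimination around an L2 logistic
  regression, dropping max(1, ⌈0.10 × remaining⌉) smallest-|coefficient|
  features per round.  Elimination continues past the target size so every
  feature receives an elimination rank, which serves as its importance.
* **rf** / **gbm** / **l2logreg** — random-forest impurity decrease,
  LightGBM split gain, and |logistic coefficient|.

A feature's votes V_j count the techniques nominating it.  The final
ranking is by descending votes; ties are broken by the importance assigned
by the *winner* technique — the one whose subset attains the highest
stratified 3-fold CV accuracy of a reference L2 logistic classifier —
and residual ties by feature id.  Zero-vote features are excluded.  By
default selection runs on the training split only.

## Model selection

Six classifiers (L2 logistic regression, SVM, multilayer perceptron,
gradient boosting, random forest, Gaussian naive Bayes) are compared on
one stratified 70/30 split, shared across all models and feature counts so
the curves are directly comparable.  For every prefix of the vote ranking
(step 2 features) each model is tuned by exhaustive grid search with
stratified 3-fold CV accuracy and scored on the held-out 30 %.  The two
best models are then re-evaluated at step 1 within ±10 features of their
peak, and the final model maximizes refined held-out accuracy; ties prefer
fewer features, then a fixed model order.  Accuracy is the sole selection
metric; precision/recall can be derived from the stored estimators but do
not drive selection.

Two grid densities are provided.  `grid_density="full"` is the complete
reference search space (e.g. 9000 gradient-boosting configurations and 104
logistic ones — a long-running mode).  The default `"reduced"` keeps 1–8
representative configurations per model (regularization sweeps for the
linear models and SVM, two depths for the tree ensembles, one MLP
architecture with two penalty values), which preserves the protocol's
structure at desk scale.  A configuration that fails to train scores 0 and
is skipped.

## Shapley-value explanation

For the selected model's margin η the attribution of feature j in row i is
the interventional Shapley value with an independent background.  When the
model is linear (η(x) = w·x + b) this has the exact closed form
φ_ij = w_j (x_ij − x̄_j) with x̄ the training-split feature means; local
accuracy Σ_j φ_ij = η(x_i) − η(x̄) then holds to machine precision, and
zero-weight features receive exactly zero.  For non-linear models a
Monte-Carlo permutation sampler is used: each draw picks a background row
and a feature ordering, switches features from background to the explained
row in order, and credits every feature its marginal margin change.  The
estimate is unbiased for the same Shapley value, its per-feature standard
error is reported, and it converges to the closed form on linear models.
Attributions are computed on the margin (log-odds) scale for the held-out
rows by default; summaries are the per-feature sum and mean of |φ|, each
inducing a ranking.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes:

* **Trajectories.**  Non-progressors receive a constant grade per knee
  (marginal skewed toward low grades: 0.55/0.25/0.12/0.08).  Progressors
  (prevalence 0.10, mirroring the strong imbalance between the stable and
  progressing clusters) receive a monotone non-decreasing trajectory with
  total increase ≥ 1 in at least one knee (left/right/both with
  probability 0.45/0.45/0.10).  Start grades favor 2 (0.2/0.2/0.6), so
  most progressors take a single-grade step — the typical structural
  change over a few years of follow-up — and the score distribution of
  progressors concentrates near 1, which keeps the optimal two-cluster cut
  at zero.  Grade marginals of real cohorts are not publicly
  characterized; these are documented free choices, not calibrations.  An
  optional per-visit ±1 grade-flip noise rate (default 0) exercises
  robustness.
* **Feature table.**  The default allocation reproduces the nine-category,
  725-feature baseline taxonomy (anthropometrics 37, behavioral 61,
  symptoms 108, quality-of-life 12, medical history 123, imaging outcomes
  21, nutrition 224, physical exam 115, physical activity 24).  A
  configurable fraction (default 0.3) of columns are 4-level integer-coded
  categoricals.  Informative numeric features are x = δ·z + ε with
  ε ~ N(0,1), z the progressor flag and δ the standardized effect size
  (default 0.8, 30 planted features); informative categoricals tilt their
  level probabilities by exp(δ·code).  All other columns are independent
  of the class.
* **Missingness.**  Completely-at-random per-column blanking; the default
  profile plants 10 columns at 30 % (above the deletion threshold) and 20
  at 5 % (below it), restricted to non-informative columns so the deletion
  rule and the planted signal do not interact.  Realized counts are
  recorded for re-checking.

Ground truth (progressor flags, planted feature ids, generator parameters)
is written alongside the data and never read by any analysis stage.

What the generator does **not** emulate: real registry variable names and
codebooks, realistic marginal shapes and correlation structure among
features, longitudinal feature drift, and missing-not-at-random
mechanisms.  Passing tests therefore demonstrate that the pipeline's
machinery is correct and leakage-free under its stated assumptions, not
that any particular accuracy level transfers to real cohorts.

## Numerical and design choices

* All stochastic steps take explicit seeds; a single master seed derives
  fixed offsets per stage, so full runs are byte-reproducible.
* Mode-imputation ties → smallest value; vote and importance ties →
  feature id; grid-search ties → first configuration in grid order; final
  model ties → fewer features, then logreg, svm, nn, gbm, rf, nbg.
* Default problem sizes (2000 subjects, balanced ≈ 400, accuracy curves up
  to 60 features, reduced grids) were chosen so a complete run finishes in
  a couple of minutes on one CPU; every size is configurable upward.
* Binarization rejects degenerate two-cluster solutions with equal means;
  `undersample` requires both classes non-empty; `knee_score` requires at
  least two visits.

## Known limitations

* The DB-based automatic k is unreliable on heavily discretized score
  distributions (see above); the labeling default therefore fixes k = 2.
* The reduced grids cannot reproduce the exact hyperparameters a full
  search would select; the full grids are available but slow.
* Attribution is margin-scale only; probability-scale attribution and
  interaction values are out of scope.
* Accuracy is the only selection metric, inheriting the corresponding
  limitation of the protocol it implements.
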
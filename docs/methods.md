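# Methods

## Model

`mvstack` implements two-level stacked generalization over multiple data
views. Base learners are trained independently, each on the original
features of its assigned view; the meta learner is trained on their
predictions. Two design commitments matter most:

1. **Out-of-fold stacking.** The meta learner's training features are the
   base learners' *validation-fold* probabilities, produced by k-fold
   stratified cross-validation inside the training set. A probability for
   sample i always comes from a model whose training folds excluded i.
   Training the meta learner on in-sample predictions would let it reward
   whichever base learner memorizes the training set best; the
   out-of-fold construction makes the meta features estimates of
   generalization behaviour instead. Per-fold models are discarded once
   their out-of-fold segment is produced.
2. **Probabilities, not labels.** Each base learner contributes its
   positive-class probability (one column per learner; the second class
   column is redundant in a binary task). Families without calibrated
   probabilities still contribute a [0, 1] score: KNN the neighbour-vote
   fraction, the modified-Huber SGD its decision value clipped to [−1, 1]
   and mapped affinely to [0, 1].

At test time every base learner is refit on the full preprocessed
training set (standard practice: the per-fold models exist only to build
meta features) and the fitted meta model maps their probability vector to
the final prediction.

### Base-learner suite

Linear: SGD logistic (SGD_LL), SGD modified-Huber (SGD_HL), KNN.
Non-linear: MLP, QDA, random forest (RF), histogram gradient boosting
(HGBC). HGBC is the only family with native support for missing values
and categorical features, so it alone is assigned the clinical view
(HGBC_clin) next to its microbial instance (HGBC_otu); all other
learners see only the microbial view, avoiding imputation and one-hot
blow-up on clinical data. Base learners run with their library defaults
— the stacking framework, not per-base tuning, is the optimization
budget — with two numerically motivated exceptions:

- every stochastic family is seeded deterministically from the pipeline
  seed (a hash fan-out, so fold-models and refits get distinct streams);
- QDA uses covariance shrinkage `reg_param = 0.1`, because per-class
  covariances are singular whenever the filtered feature count reaches a
  fold's class count and current scikit-learn refuses to fit them bare.

Learners that support per-class weights (both SGDs, RF, both HGBCs)
receive balanced data-space weights `w_c = n / (2 n_c)`; re-weighting
biases training toward the rare class without discarding samples
(under-sampling) or fabricating them (over-sampling).

### Preprocessing (microbial view only)

Fitted on training rows only, in order: remove zero-variance columns;
Yeo-Johnson power transform with standardization (Yeo-Johnson rather than
Box-Cox because abundance tables are full of exact zeros); per-feature
one-way ANOVA F-test between the two classes with Benjamini-Hochberg FDR
correction, keeping features with adjusted p ≤ α. Defaults α = 0.05,
`fdr_bh`; Bonferroni and `none` are selectable, and a stricter α
reproduces the heavier-filtering regime at the cost of discarding
features a multivariate learner might have used. The clinical view passes
through untouched (HGBC consumes it natively). If *nothing* passes the
filter — routine on signal-free data — the pipeline falls back to plain
variable ranking (the 10 smallest raw p-values) rather than aborting: the
filter's job is dimensionality reduction, not deciding whether modelling
is worthwhile. The ANOVA filter is deliberately fitted once on the full
training set (the filtered matrix is shared by the out-of-fold stage),
so filter selection is part of training-set state; the held-out test
split never influences it.

No imputation anywhere: missing clinical values stay missing and reach
HGBC_clin as its native missing category; unseen categorical levels at
test time map to that same missing category.

### Meta learner

Elastic-net logistic regression, grid-searched over
C ∈ {10⁻³, 10⁻², …, 10³} × l1_ratio ∈ {0, 0.25, 0.5, 0.75, 1} with
stratified k-fold CV, scored by average precision, refit at the best
point. A linear meta learner keeps the second interpretation level
available (its weights *are* the base-learner importances); a
random-forest meta learner is available as a configuration for
comparison but surrenders that interpretability. k defaults to 5,
stratified, shared with the out-of-fold stage.

## Evaluation

Average precision (step-sum summarization of the PR curve, no
interpolation) is the headline metric; under class imbalance it degrades
gracefully where ROC-style areas flatter a model, and its uninformative
baseline is simply the positive prevalence (`random_ap`), drawn as the
red reference line on PR plots. Per-model AP is reported on the training
split, per-fold validation splits (median over folds) and the held-out
test split; `overfit_gap` is median train AP − median validation AP.
For the stacked row of CV summaries the fold model is built by a nested
out-of-fold construction entirely inside the k − 1 training folds, so
its validation score is as honest as the base learners'.

Classifier agreement uses MCC between 0.5-thresholded predictions of
every model pair plus the labels, with the zero-denominator convention
MCC = 0 (needed when a model predicts a single class). Diversity —
low off-diagonal MCC with decent label-row MCC — is the regime in which
stacking has something to combine.

## Interpretation

Meta weights are normalized by the maximum absolute weight (top learner
= ±1, signs kept) and ranked. Permutation importance shuffles one
original feature column at a time (10 repeats by default, seeded),
pushes the mutated table through the *entire* fitted pipeline — filter,
transform, base learners, meta learner, no refitting — and reports
baseline AP minus permuted AP per repeat with the median. It is computed
on the training set. Features the filter discarded are reported with
importance exactly 0 rather than omitted, keeping reports comparable
across α settings (they cannot influence the model, and skipping their
permutations keeps the computation proportional to the kept set).

## Synthetic cohorts

The generator draws labels first (exactly `round(n · positive_fraction)`
positives) and features conditional on them, so every planted effect is
auditable.

- **Microbial view** — zero-inflated log-normal abundances. The
  informative subset co-varies through one latent "dysbiosis" axis
  z = microbial_effect · y + N(0, 1): each informative OTU loads on z
  with alternating sign in both its log abundance and its presence
  log-odds (carriage prevalence moves with abundance). The shared axis is
  the realistic part — disease-associated taxa shift as a community —
  and it is also what keeps per-feature effects FDR-detectable at small n
  while capping the view's aggregate separability: with independent
  per-feature effects, any effect large enough to survive the filter
  would make the view trivially separable in aggregate.
- **Clinical view** — numeric features N(clinical_effect · y, 1) on the
  informative slots (numeric slots fill first), three-level categorical
  features with a class-tilted level distribution on the remainder of the
  informative budget, and completely-at-random missingness at
  `missing_rate_clinical` in this view only.

Defaults: microbial_effect = 2.0, clinical_effect = 1.5 — a moderately
strong community-level microbial shift next to one moderately strong
clinical marker, chosen so that at the small preset's size (120 samples)
the filter retains a non-trivial feature subset, no single view is
sufficient on its own, and the two views stay complementary. The cohort
presets `ibd-like` (535 samples, 17% positive, 6737 OTUs, 1 numeric + 6
categorical clinical features, ~6% clinical missingness ≈ 223 cells) and
`crc-like` (291, 41%, 5982, 2 + 7, ~5 missing cells) copy the two reference
cohort designs' shapes; the `-small` variants (120 samples, 300 OTUs) keep
imbalance and signal structure at a size where a full pipeline fits in
seconds — these are the sizes the test suite and multi-seed property
checks run at. A `null_config` helper zeroes both effects for
chance-level calibration checks.

What the generator does **not** emulate: compositionality (no total-sum
constraint), phylogenetic correlation beyond the single latent axis,
taxonomy, informative missingness, batch effects. Passing tests on these
cohorts therefore demonstrate that the machinery is correct and that the
pipeline recovers planted structure under the stated noise model — not
that any particular performance level will transfer to real cohorts.

## Numerical and procedural choices

- Stratified 80/20 split by default (preserves the imbalance the metrics
  assume); a flag disables stratification. Splits, folds, learner seeds
  and permutation draws all derive from one pipeline seed via hashing,
  so reruns are byte-identical.
- Soft-vote ties (mean probability exactly 0.5) go to the negative
  class, the reference class in both cohort designs.
- One shared filtered microbial matrix feeds all microbial-view learners.
- Fold count k must not exceed the minority class count (error).
- A single-class data subset is a warning at container level; every
  operation that genuinely needs both classes raises its own error.
- `anova_filter` assigns F = 0, p = 1 to features with no between-group
  variance, so they are filtered at any usual α.
- MCC zero-denominator → 0; AP requires both classes present.

## Limitations

- Two views are wired throughout the defaults; the container admits more,
  but the suite builder and tests do not cover additional views.
- No per-base-learner hyperparameter search, no probability calibration,
  no multiclass support, no compositional transforms (CLR/ILR) — the
  microbial view is modelled on the raw abundance scale after the power
  transform.
- Permutation importance on very wide kept sets is linear in
  (kept features × repeats) pipeline evaluations.
- The bundled generator is the only data source exercised by the tests;
  real-cohort adapters are limited to the delimited-table loader and its
  sidecar schema.
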
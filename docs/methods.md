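# Methods

`mfeast` ranks the features of a feature-by-sample expression matrix by their
ability to discriminate two sample classes, using an ensemble of twelve
filter-, wrapper-, and embedded-type selection algorithms under
cross-validation, and evaluates selected panels downstream. This note
records the model, the defaults that matter, and the design choices that
were genuinely open.

## Input model and preprocessing

The pipeline consumes a complete, non-negative matrix of normalized
expression values (RSEM-like units for RNA-seq), features in rows. Two
preprocessing steps mirror the usual biomarker workflow:

* **Low-expression filter.** The threshold is the median over *every cell*
  of the matrix (a single pooled median, not per-feature medians). A feature
  is removed when its value is strictly below the threshold in strictly more
  than `fraction * n_samples` samples (default fraction 0.90). Both
  comparisons are strict; the boundary cases (a feature exactly at the
  threshold, or low in exactly 90% of samples) are kept. The comparison
  direction is not observable from the rule's usual description, so the
  literal strict reading was chosen and is pinned by tests.
* **log2 transform.** Zeros are replaced by the smallest non-zero value in
  the whole matrix, used as-is (not halved); the replacement is configurable
  via `log2_transform(zero_replacement=...)`. All outputs are finite.

`zscore_scale` (per-feature, n−1 standard deviation, constant features map
to zeros) is applied inside the classifier evaluation with training-fold
statistics only; `median_center` exists for heatmap display.

## The twelve scorers

**Univariable filters** (per-feature, no learner):

* *ROC criterion* = `2·|AUC − 0.5|` where AUC = P(class-b value > class-a
  value) with half-credit ties, so the score spans [0, 1] and is symmetric
  under label swap and sign flip. The `|AUC − 0.5|` variant would span only
  [0, 0.5]; the doubling honours the convention that a perfect univariable
  discriminator scores 1.
* *Wilcoxon criterion* = |z| of the Mann–Whitney U count with the plain
  variance `n_a·n_b·(n_a+n_b+1)/12`. No tie correction is applied to the
  variance — the raw score is only used after min–max normalization over
  features, where a common correction factor would cancel anyway.
* *Mutual information* (bits) between the feature discretized into 10
  equal-width bins over its observed range and the class label, plug-in
  estimate. Equal-width binning was chosen over equal-frequency because it
  is deterministic and parameter-free given the bin count; the bin count is
  configurable.
* *ReliefF*, binary form: features range-scaled to [0, 1]; every sample
  serves as a reference (no sampling, hence deterministic); k = 10 nearest
  hits and misses under Manhattan distance over all features, distance ties
  broken by ascending sample index; k is clipped to class size − 1 when a
  class is small. Weights lie in [−1, 1].

**Sequential wrappers** (linear SVM C = 1; k-NN k = 5 Euclidean; Gini
decision tree, unlimited depth; QDA with a 1e-6 ridge on each class
covariance): greedy forward selection minimizing mean CV misclassification,
starting from the majority-class baseline, stopping when no candidate
*strictly* improves the criterion or a budget of min(50, p) features is
reached. Candidate ties take the earliest feature in matrix order. A fold
where a learner cannot fit (e.g. singular QDA covariance) scores the worst
possible rate 1.0 rather than aborting. The search repeats five times with
re-randomized stratified partitions; the "iterations" setting for
sequential algorithms means these full-search repeats, whose votes are
averaged — this is what produces fold-stability, and it makes the wrapper
score an interpretable selection frequency in {0, 1/5, …, 1}.

The k-NN and QDA searches use incremental evaluators (cached squared
distances; class-centered Gram products) that are algebraically identical
to refitting from scratch; the decision tree and SVM use scikit-learn
estimators directly.

**Embedded tree ensembles** (100 learners each):

* *Bagged-tree permutation importance* ("treebagger"): per bootstrap tree
  (√p features per split), the increase in out-of-bag error when one
  feature's OOB column is permuted; the per-tree mean increase divided by
  its standard deviation over trees (0 when the deviation is 0), negatives
  clipped. Features a tree never splits on contribute exact zeros.
* *Split-gain importances* under three ensembles: plain bagging
  (full-depth Gini trees), GentleBoost (depth-1 regression stumps fit by
  weighted least squares to the ±1 response, weights updated
  `w ← w·exp(−y·f_t(x))` and renormalized), and RUSBoost (AdaBoost-style
  rounds trained on the minority class plus a 1:1 without-replacement
  undersample of the majority, default depth 3; a round with weighted error
  ≥ 0.5 is resampled up to 10 times before stopping early). Importance is
  the sample-weighted impurity decrease summed over every split on the
  feature across all learners.

## Cross-validation and aggregation

Folds are stratified by class (k-fold and holdout), deterministic given the
scheme seed; leave-one-out and resubstitution are also available. Every
stochastic sub-procedure derives its own stream from
(master seed, method name, fold/repeat index), so the whole ensemble is
reproducible byte-for-byte from one integer.

Raw-score methods (filters and importances) run per fold on training
samples only and are min–max normalized **over features within each fold**
(an all-equal vector normalizes to all zeros), then fold-averaged. Min–max
within fold is what makes |z|-scale and split-gain-scale scores
commensurable with the [0, 1] filters before voting. Wrapper methods use
the CV scheme as the internal criterion of the search, so their
repeat-averaged membership is already a [0, 1] vote and is not re-normalized.

The **ensemble score** of a feature is the unweighted mean of its per-method
scores; the ranking is built greedily by repeatedly extracting the
remaining feature with the largest ensemble score. Ties break toward the
feature with the better (smaller) mean per-method rank position, then
lexicographically by id, making the permutation total and deterministic.
The aggregation formula itself — mean of per-fold-normalized method scores
with greedy extraction — is this package's reconstruction of an ensemble
vote; whether such a vote should operate on scores or on ranks is a
genuinely open choice, and the score-based mean was adopted because it
preserves the magnitude information of the univariable scorers. Two
consequences pinned by tests: a method that scores all features identically
cannot change any rank, and a feature dominant under every method in every
fold receives rank 1.

`select_features` supports all / top-fraction (ceil(fraction·p) features in
rank order) / custom-list selection.

## Panel evaluation

`classify_panel`: stratified k-fold (default 10), features z-scored with
training-fold statistics, linear SVM (C = 1), and per-fold accuracy,
precision, recall, and F1 with the first-named class of the comparison as
the positive class (reported explicitly, since the convention is otherwise
arbitrary). F1 is defined as 0 when precision + recall = 0. Summary
statistics are unweighted fold means and n−1 standard deviations.

`cluster_samples`: sample–sample distance = 1 − Spearman correlation of
expression profiles over the panel (average-rank ties; range [0, 2]),
agglomerated with unweighted average linkage (UPGMA) via
`scipy.cluster.hierarchy`; a sample with zero variance across the panel has
undefined correlations and is reported by name. `embed_samples` delegates
to scikit-learn t-SNE with a seeded state and perplexity
min(30, (n−1)/3); its contract is shape and determinism only.

## Cohort statistics

Categorical clinical variables are tested with the uncorrected Pearson
chi-square (`scipy.stats.chi2_contingency`, `correction=False`) —
recomputation of the bundled reference cohort tables confirms the published
statistics only without the Yates correction — with a flag whenever any
expected count is below 5. Ordinal/ratio variables use Kruskal–Wallis with
average-rank ties and tie correction; the all-identical degenerate case
returns H = 0, p = 1. Missing values are dropped per variable, so each test
reports its own n.

## Synthetic data

The generator draws `value = 2^(log2(base_mean) + class_shift + ε)` with
ε ~ N(0, dispersion) per cell: log-normal expression with a multiplicative
class effect, matching the pipeline's normalized-input stage rather than a
negative-binomial count model. Planted features receive class shifts of
±effect/2, so the expected log2 difference between classes equals `effect`.
A `zero_rate` fraction of entries is zeroed uniformly at random to emulate
dropout, independently of the mean (mean-dependent dropout is a non-goal).

Defaults — 60 samples per class, 10 planted among 500 features, effect 2.0
log2 units (a 4-fold expression change, typical of a strong biomarker),
dispersion 1.0 (log2-scale biological + technical spread), base mean 100,
zero rate 0.2 — model a filtered, highly expressed gene panel in a
moderately sized two-class cohort. What the generator does *not* emulate:
feature–feature correlation structure, batch effects, mean–variance
coupling, and class-imbalanced dropout; tests passing on this model
therefore demonstrate algorithmic correctness and recovery power under
idealized independence, not performance guarantees on real cohorts.

## Benchmarks and problem sizes

The repository's acceptance checks run two end-to-end benchmarks at the
package's default scale: (1) planted-feature recovery — all twelve methods,
5-fold CV, five sequential repeats on the default 500-feature spec, at
least 9 of 10 planted features expected in the top 25 ranks; (2) panel
utility — on a 574-feature spec, the top-10% panel (58 features) must beat
all 574 features in 10-fold linear-SVM accuracy. Each benchmark takes a few
minutes on one CPU; these sizes were chosen to exercise the full ensemble
at a realistic feature count while keeping a complete test run comfortably
interactive.

## Known limitations

* Binary comparisons only; multiclass use is one-vs-all or hierarchical
  composition by the caller.
* Wrapper learner hyperparameters are fixed defaults (no internal grid
  search); the hook exists in configuration but optimization is not
  implemented.
* The sequential searches dominate runtime (roughly p candidate refits per
  added feature per fold per repeat); for tens of thousands of features
  exclude the `*_sfs` methods, as the interface encourages.
* Importance magnitudes are not comparable across embedded variants before
  per-fold min–max normalization; only normalized scores are aggregated.
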
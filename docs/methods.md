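# Methods

## Pairs and the gold standard

A protein pair is undirected and stored canonically (lexicographic
order, no self-pairs); all de-duplication, set algebra and file
round-trips operate on canonical pairs. Positives are the union of any
number of curated pair sources with per-pair provenance. Negatives
follow the localization-incompatibility assumption: every
plasma-membrane × nucleus cross pair not already known to interact is
treated as non-interacting. Two refinements the rule itself does not
dictate: proteins annotated to *both* compartments are excluded (a
dual-localized protein falsifies the incompatibility premise), and the
negative space can be consumed lazily, since at proteome scale it runs
to ~10⁷ pairs. Balanced training sets are drawn by seeded uniform
subsampling without replacement — the package makes no attempt to model
how any particular curated corpus was thinned, so the neutral choice is
uniform. Process-specific protein sets are selected by case-insensitive
substring match on term *names* (e.g. "autophagy" also matches
"macroautophagy"), optionally unioned with an external curated list.

## Evidence features

* **Co-expression**: Pearson correlation over samples where both genes
  are observed; undefined (missing) when either gene is absent, fewer
  than 3 samples overlap, or a profile is constant. Rows are taken in
  canonical pair order so the value is exactly swap-invariant.
* **Minimal shared GO / KEGG term**: the member count of the smallest
  term annotating both proteins; missing when they share no term. The
  alternative reading — the smaller of the two proteins' annotation
  counts — ignores sharing altogether and is not used.
* **Diversity of functions**: |GO(a)| + |GO(b)|, a pair-level sum.

Missingness is informative (a pair sharing no term is *evidence*, not a
defect), so discretization reserves a dedicated bin for it.
Equal-frequency binning (default 5 bins) is fitted on training values
only; duplicate quantiles merge, so degenerate features may end with
fewer effective bins, and bin index is monotone in the raw value.
Feature informativeness is scored with a one-way ANOVA F statistic of
the raw feature against the label (a filter-strategy score with a
p-value; for two classes F = t²).

## Classifiers and training protocol

All three models are scikit-learn-compatible estimators and emit scores
in [0, 1]:

* **Categorical naive Bayes** on binned features; conditionals are
  (count + α)/(class total + α·B) with Laplace α = 1 by default. The
  category set per feature defaults to the distinct values observed in
  training (so B in the denominator is the number of observed bins);
  the pipeline passes the binning scheme's full category count
  explicitly so a missing-bin unseen in training still scores. A bin
  value outside the category set is an error, never silently smoothed.
* **Decision tree**: CART-style greedy Gini-decrease maximization over
  midpoint thresholds, ties broken by lowest feature index then lowest
  threshold (this makes the grown tree reproducible against exhaustive
  search); score = leaf positive fraction. Tunables: max depth
  (default 6), min leaf size (default 5).
* **k-NN**: Euclidean distance on z-standardized features, odd k
  (default 5), exact distance ties broken by training-row order. It
  consumes *raw* features: missing values are imputed with the training
  median and a 0/1 missingness indicator per feature is appended, so
  missingness still carries signal under a metric model.

Protocol: stratified 7:3 train/test split; stratified 10-fold
cross-validation on the training part; misclassification measured at
score threshold 0.5. A model is accepted iff training error ≤ 0.15 and
testing error ≤ 0.15 (boundary inclusive). The learning-curve operation
defines the validation score at fraction f as 1 − (k-fold CV error on a
stratified subsample of size f·n), so its f = 1 point coincides with
plain CV by construction; fractions leaving too few samples per class
for the fold protocol are skipped with a warning.

## Evaluation

Predicted-positive means score ≥ threshold (inclusive, for determinism
at boundaries). ROC is swept over all distinct scores; the trapezoid
AUC equals the Mann–Whitney concordance P(s⁺ > s⁻) + ½P(tie). The PR
curve reports, for each achieved recall, the best precision any
threshold attains there (lowering a threshold at fixed recall only adds
false positives), with precision → 1 as recall → 0 by convention. The
operating threshold is the observed score maximizing F1 (lowest score on
ties); Youden's J is available as an alternative rule. The "accuracy at
the optimal threshold" reported next to the PR curve is overall
accuracy at that operating point.

## Consensus

Each accepted model thresholds candidates at its own max-F1 operating
point (a shared fixed threshold is available); the consensus is the
strict intersection of the per-model positive sets, reported with all
seven Venn region counts, and already-known interactions are removed
from the final novel set. Lowering any threshold can only grow the
consensus; exclusion of known pairs is idempotent.

## Network modules

Vertices are weighted MCODE-style: the densest core (highest k) of the
closed neighborhood contributes weight k × density. Modules grow
breadth-first from the highest-weight unassigned seed over neighbors
whose weight is ≥ (1 − cutoff) × seed weight (cutoff 0.2, matching the
plugin's node score cutoff), each vertex joining at most one module;
candidates are then haircut (iterative degree-1 removal) and must retain
a non-empty 2-core. One deliberate refinement over the literal plugin
behaviour: cut (bridge) edges are removed from a candidate module before
scoring and each remaining component's 2-core becomes a module of its
own. A bridge lies on no cycle and therefore belongs to no densely
interconnected complex; without this step two equally dense complexes
touching through a single spurious edge fuse into one diluted module,
because their vertices carry identical weights and the expansion cannot
tell the bridge apart from an internal edge. Modules are scored
density × size and ranked descending (ties: larger, then lexicographic
seed); the top 4 are reported by default, all are written. K-means was
not layered on top: no feature space for it is defined in this setting,
and the seeded-expansion algorithm already yields disjoint modules.

## Synthetic data

Two generation tiers, both fully seeded and deterministic.

**Feature level.** Each feature gets a positive and a negative
distribution from {normal, truncated normal on [−1, 1], geometric over
bins, negative binomial, point mass}, plus per-class missingness rates
and a class prevalence. Because the densities are known, the exact
Bayes posterior is computable per row and upper-bounds any trained
model's AUC; for one Gaussian feature (μ⁺ − μ⁻ = Δμ, common σ) the
oracle AUC has the closed form Φ(Δμ/(σ√2)).

**Entity level.** A universe of `n_proteins` with: one compartment per
protein (plasma membrane 25%, nucleus 25%, cytoplasm 50%); GO terms
with bounded-Pareto sizes (exponent 2, sizes 3–40) plus a few terms
named after the target process covering a configurable process fraction
(60%); KEGG pathways likewise; an expression matrix; and planted
interactions organised as *disjoint complexes* of 2–4 proteins.
Proteins of one complex share a latent factor, x = λf + ε with ε ~
N(0, σ²), so every planted pair has expected Pearson λ²/(λ² + σ²) and
no unplanted pair inherits correlation (complexes are cliques and do
not overlap). Planted pairs are co-assigned to a small GO term and
KEGG pathway with probability `p_share` and are never
localization-incompatible, so the negative rule cannot contradict the
ground truth. A configurable fraction of proteins (5%) is absent from
the expression matrix, exercising the missing-data path end to end.

Benchmark defaults — λ = 0.8, σ = 1, 80 samples (planted-pair r ≈ 0.39),
p_share = 0.6, 500 proteins, 250 planted pairs — put the induced feature
separability in the mid-0.9s AUC range: strong enough that the 0.15
error ceiling is attainable, weak enough that it is not trivial. The
benchmark run withholds 30% of planted pairs from the known-positive
list and mixes them into the candidate pool with two random
non-interacting decoys per hidden pair, so consensus precision and
recall can be measured against ground truth.

What the generator does **not** emulate: count-distributed RNA-seq
noise, annotation bias toward well-studied proteins, GO graph structure
(ancestor propagation), overlapping complexes, and database errors in
the gold standard. Passing tests therefore demonstrate correctness of
the machinery and recoverability under a faithful factor-model signal —
not performance on any real interactome.

## Problem sizes and numerics

The test suite and the acceptance script run the full pipeline on the
500-protein benchmark (about a second per run) and use 50k rows only
for the closed-form Monte-Carlo check; oracle-equivalence checks use
exact comparisons (1e-10/1e-12) on small instances. Quantile cut
points outside a feature's open value range are dropped (constant
features collapse to one bin); posterior normalization falls back to
the class prior when a zero-probability joint occurs under α = 0; all
derived seeds stay below 2³¹.

## Known limitations

* The localization negative rule manufactures negatives that are easier
  than random non-interacting pairs in real data; measured errors are
  optimistic in the same way the underlying design is.
* Strict three-way consensus trades recall for precision by
  construction; no soft voting is provided.
* The module algorithm reports vertex-disjoint modules; overlapping
  complexes are split by first claim (seed weight order).
* Categorical NB treats bins as unordered; ordinal information inside
  the binning is used only by the tree and k-NN.
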
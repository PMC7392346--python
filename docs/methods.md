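# Methods

## Problem setting

The package classifies RNA sequences (50–250 nt, the riboswitch size band)
into families under severe class imbalance. The pipeline is: k-mer count
featurization → correlation-based feature selection → grid-searched
multiclass classification, run twice on identical splits — once on the data
as-is and once with SMOTE oversampling applied inside the training folds —
followed by a paired statistical comparison of the two arms.

## Featurization

Counts are raw overlapping window counts (stride 1), not frequencies and
not length-normalized: counts are the simplest faithful reading of k-mer
"frequency counts" over sequences of comparable length, and they keep the
planted-signal arithmetic of the synthetic benchmark exact. Columns are
ordered by ascending k and lexicographically (A<C<G<U) within each k, so
the 5,460-column layout for 1 ≤ k ≤ 6 is stable across runs and platforms.
Windows containing an ambiguous residue (N) are skipped rather than imputed
— skipping cannot fabricate counts, at the cost of slightly undercounting
near ambiguity. Reverse complements are distinct features (these are
single-stranded RNAs, not genomic reads).

## Feature selection

CFS needs discrete variables for its entropy-based correlation. Counts are
discretized per feature by equal-frequency binning (default 10 bins) using
midranks: each distinct value's bin is `ceil(midrank·bins/n) − 1`, bins are
compressed to consecutive indices, and cut points (midpoints between
adjacent values whose bins differ) are stored so held-out data is binned
with the training cuts. Midrank binning is used instead of interior
quantiles because quantile cuts collapse a skewed two-valued feature into a
single bin, silently zeroing its correlation with the class.

The correlation measure is symmetrical uncertainty (SU), the canonical CFS
choice, defined as 0 when both variables are constant and clipped to [0,1]
against floating-point noise. The search is forward best-first with
backtracking: an open list of subsets keyed by merit, the best subset
expanded by every unused feature, termination after `max_stale = 5`
consecutive expansions without a global improvement (ties broken by column
order, so the search is deterministic). Pairwise SU vectors are computed
lazily and cached per selected feature, which keeps the search linear in
features-per-expansion rather than quadratic upfront. On instances of ≤ 6
features with `max_stale ≥ 6` the search recovers the exhaustive-search
optimum on every random instance tested; no optimality guarantee exists in
general. Selection is fit on the training split only and applied to the
test split by column subsetting.

## SMOTE

Implemented from scratch: per under-target class, parents are chosen
round-robin over the class's rows in original order, the neighbour is drawn
uniformly from the parent's k = 5 nearest same-class neighbours (Euclidean;
distance ties resolve to the lower row index; k clamps to class size − 1),
and the interpolation coefficient is u ~ U[0,1). The default target
equalizes every class to the majority count. Synthetic feature values stay
real-valued — classifiers consume geometry, not counts — with an optional
rounding mode for strict count semantics. Originals are passed through
unchanged ahead of all synthetic rows, and each synthetic row records its
parent pair, which is what the betweenness and leakage tests audit. A class
with a single member cannot be oversampled and is an error by design.

## Cross-validation protocol

The 70/30 split is stratified per family by default (round(0.3·n) test
members per family; singletons stay in training with a warning), because a
five-member family can vanish from an unstratified 30 % sample; an
unstratified mode exists. Folds are stratified by dealing each class's
shuffled members round-robin, so classes smaller than the fold count appear
in as many validation folds as they have members and fold scores are
computed over the classes present in that fold. The fold partition depends
only on (labels, fold count, seed), never on the balancing flag or the
hyperparameter combination, which is what makes the two arms comparable.
Per-fold balanced training sets are built once and reused across all grid
combinations. All randomness flows from one master seed through named
substreams (split, folds, per-fold SMOTE, final SMOTE, classifier init), so
a run is bit-reproducible and stages do not perturb each other.

The six classifier families and their default grids are the published ones
(KNN k ∈ {2..16}; SVM kernel ∈ {linear, poly, rbf, sigmoid}; RF 500–2000
trees × depth 10–20; GB 500–2000 trees × learning rate {0.01, 0.1, 0.05} ×
depth {7, 9, 11, 15}; MLP three hidden layers of 80/100/150 × L2
{1e-3, 1e-4} × {adam, sgd} × tol {1e-8, 1e-7, 1e-6}; Gaussian NB variance
smoothing {1e-16, 1e-14, 1e-12}). The classifiers themselves are
scikit-learn's; the package's contribution is everything around them. The
fast profile (k ≤ 4; KNN {4, 8}, RF 100×10, GNB 1e-12) is the scaled-down
study condition used by the quick tests and the acceptance script.

## Evaluation

Metrics are one-vs-rest per family. The default "standard" mode uses the
conventional definitions (Sen = TP/(TP+FN), Spec = TN/(TN+FP)); the
"paper" mode reproduces verbatim a published formula set in which
sensitivity is TP/(TP+FP) and specificity TN/(TP+FN) — the latter is not
bounded by 1 and values above 1 are flagged, never clipped, so the mode is
usable for fidelity audits only. 0/0 ratios are defined as 0 so families
absent from a fold do not poison macro means. Macro F is the unweighted
arithmetic mean of per-family F1.

The Wilcoxon signed-rank test drops zero differences, midranks ties, and
uses an exact null distribution (subset-sum dynamic programming over
doubled midranks) for n ≤ 25 and a tie-corrected normal approximation
(no continuity correction) above. Two-sided p = min(1, 2·min(P≤, P≥)).
No multiple-testing correction is applied across the four metrics; results
are reported per metric with star levels at 0.05/0.01/0.001.

## Synthetic benchmark

A family is a background composition (default uniform), two distinct random
signature k-mers (4–6 nt), and an insertion process: per signature, a
Poisson(rate·L/100) number of copies overwrite the background at uniform
positions. Overwriting (no indels) keeps lengths exact and the planted
signal countable. The default rate of 4 insertions per signature per 100 nt
makes family motifs near-universal among members — as conserved aptamer
motifs are — and puts the benchmark where real riboswitch families sit:
largely classifiable (macro F ≈ 0.8–0.95 under the fast profile), with the
minority families the locus of failure under imbalance. The
imbalance-shaped preset interpolates 16 family sizes geometrically from
round(4826·scale) down to max(5, round(39·scale)); at the default scale
0.02 that is 97 down to 5 members (517 sequences).

What the generator does **not** emulate: secondary structure, covariation,
indel variation, phylogenetic relatedness between sequences, and
composition bias shared across families. Passing tests therefore show that
the pipeline recovers planted compositional signal under imbalance — not
that it reaches any particular accuracy on real Rfam families.

## Numerical and degenerate-input choices

SU is clipped to [0,1]; merit uses the raw pair-sum form
sum_rcf/√(s + 2·sum_rff). A dataset whose features are all constant yields
an empty selection with a warning instead of an error. Grid winners break
ties by declaration order. Reports are written with sorted JSON keys and
fixed float formats; the run manifest records SHA-256 digests of every
report so two runs can be compared byte-for-byte (timings live only in the
manifest).

## Known limitations

- Best-first CFS is a heuristic; on thousands of features the selected set
  and its size are sensitive to the discretization and `max_stale`.
- The full grids are expensive (hundreds of combinations × 10 folds); the
  fast profile is the practical default for exploration.
- The paper-mode metric formulas are reproduced for auditability but are
  not meaningful as performance measures (specificity unbounded).
- With 16 paired families, the Wilcoxon comparison of a single run has
  limited power; directional claims should be aggregated over seeds, as the
  acceptance script does.
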
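# Methods

## The model

`wmrca` discovers molecular subtypes from multi-omics data (mRNA, miRNA,
lncRNA, DNA-methylation, copy-number layers) in three stages.

**1. Per-layer resampling consensus clustering.** For each candidate
cluster number K in a grid (default 2..6), samples are repeatedly
subsampled without replacement (default fraction 0.8, 250 repetitions) and
clustered with a base algorithm — hierarchical clustering with complete
linkage on 1 − Pearson correlation between sample profiles by default;
k-means and a Voronoi-iteration k-medoids (PAM-style) are alternatives.
The consensus matrix entry M(i, j) is the fraction of repetitions in which
samples i and j were co-clustered, among those where both were drawn.
Pairs never co-sampled (essentially impossible at the defaults) are set to
0 with a warning. Final labels at a given K come from agglomerative
clustering of the dissimilarity 1 − M, cut into exactly K groups and
renumbered by first appearance so labelling is deterministic.

**2. Best-K selection by weighted majority voting over ten indices.** Ten
internal validation indices are evaluated over the K grid:

| index | source | direction |
|---|---|---|
| PAC | consensus matrix | minimize |
| cophenetic index | consensus matrix | maximize |
| mean silhouette | 1 − Pearson dissimilarity | maximize |
| Calinski–Harabasz | numeric matrix | maximize |
| entropy of cluster sizes | labels | maximize |
| Dunn, Dunn 2 | dissimilarity | maximize |
| within/between ratio | dissimilarity | minimize |
| Pearson gamma | dissimilarity | maximize |
| gap statistic | numeric matrix | one-SE rule |

PAC(x1, x2) = CDF(x2) − CDF(x1) over the exact pair values of M, with
default bounds (0.1, 0.9): these are the field-standard choices for "close
to 0" and "close to 1", and they are configurable. Each index casts a
one-hot vote d_{t,j} for its preferred K (ties toward the smallest K;
undefined values skipped). The vote total for K is Σ_t w_t d_{t,j}; the
prediction indicator is 1 when that total reaches the threshold θ, and the
selected K is the argmax of the totals, ties again toward the smallest K.
Defaults are w_t = 1 for all ten indices and θ = 1, so the default rule is
plain majority voting with a one-vote reporting threshold.

**3. Cluster-of-clusters (COCA) integration.** Per-layer assignments at
the selected Ks are one-hot encoded into an N × C binary membership matrix
(C = Σ per-layer K; every row sums to the number of layers). Stages 1–2
are repeated on this binary matrix — rows as samples, 1 − Pearson distance
by default (Jaccard available) — and the second voting round fixes the
final subtype count and labels. With L layers the pipeline therefore runs
L + 1 voting rounds. Layers are first reduced to their common samples;
a sample must have an assignment in every layer for its membership row to
be defined, so intersection is the default policy.

`wmrca_plus` is the same pipeline with designated layers restricted to a
gene set (e.g. lipid-metabolism genes) before clustering, recording which
layers were restricted.

## Index conventions and numerical choices

- **Cophenetic index.** The voting statistic is the cophenetic
  *correlation* between 1 − M and the dendrogram's cophenetic distances
  (maximize; near 1 means the consensus is faithfully hierarchical). The
  plain mean of the pairwise cophenetic distances is also computed and
  reported as a secondary diagnostic, but does not vote: the mean by
  itself has no defensible direction as a K-selection rule, while the
  correlation does.
- **Entropy** is −Σ p_k ln p_k over cluster-size fractions and is set to
  maximize (balanced partitions preferred). Its direction is a genuine
  design choice; it is one vote among ten and configurable.
- **Dunn-type degeneracies.** When every cluster is perfectly tight
  (zero within-cluster dissimilarity, as happens on the binary COCA
  matrix with duplicated rows), Dunn and Dunn 2 are +inf if separation is
  positive, NaN if everything is tied; NaN values are skipped in voting.
  Singleton clusters have silhouette 0 by convention; indices undefined
  for a partition (e.g. Calinski–Harabasz at K = N) return NaN.
- **Gap statistic.** W_K is the pooled within-cluster dispersion
  (equivalently, sum of squared deviations from cluster centroids);
  reference datasets are drawn uniformly over the per-feature range box
  and clustered hierarchically (complete linkage, Euclidean), B = 50 by
  default; selection uses the one-standard-error rule with
  s_K = sd_b(log W*) √(1 + 1/B), falling back to the argmax. W = 0
  (perfect clusters) yields Gap = +inf, which the rule handles naturally.
- **PCA feature scoring** works on feature-centered (not per-feature
  standardized) data: each feature scores Σ over the leading components of
  |loading| × component standard deviation, so a feature that drives a
  large share of sample-to-sample variance ranks first and agrees with
  variance ranking in the dominant-feature limit.
- **k-NN imputation** uses plain Euclidean distance over the features
  observed in both samples (no rescaling by the co-observed fraction), and
  imputes a missing entry as the mean of the k nearest samples that
  observe that feature.
- **Missingness filter** reads its threshold (default 0.8) as the maximum
  tolerated missing fraction: a feature is dropped when missing-fraction >
  threshold. The complementary reading — keep features observed in at
  least that fraction of samples — exists in practice and is available as
  `mode="min_observed"`.
- **CNV projection** treats segment and gene intervals as 1-based
  inclusive (SEG/GTF convention) and aggregates by overlap-length-weighted
  mean (unbiased for genes spanning breakpoints); `max_abs` is available
  for workflows that prefer the extreme call.
- **FSQN** maps the rank-r target value of each feature onto the
  corresponding quantile of the reference feature (linear interpolation
  between order statistics when sample counts differ, average ranks for
  ties). The map is monotone, hence idempotent.
- **θ and the weights** are unconstrained non-negative numbers. With ten
  unit weights the totals range up to 10, so θ is not forced into [0, 1];
  the prediction indicator is reported per K but only the argmax
  determines the selected K.
- **Determinism.** Every run draws all randomness (subsampling, k-means
  and k-medoids initialization, gap references) from one root seed via
  per-stage child seeds, so a fixed config reproduces results bit for bit.

## The synthetic-data generator

`simulate_multiomics` plants k_true subtypes shared across layers. Each
layer is Gaussian noise (sd 1 by default) in which an informative fraction
of features (default 0.4) receives a subtype-specific mean shift: one
subtype per feature, chosen at random but fixed across samples, is shifted
by `effect_size` sd units. Methylation-like layers are logistic-squashed
to (0, 1); missingness is completely at random. Defaults emulate a
strong-signal desk-scale study: 60 samples, three layers of 120/80/100
features, effect size 8 sd — large enough that every resampled clustering
recovers the planted structure, which is what the recovery contracts
assert. `simulate_cnv_segments` tiles chromosomes with segments whose
values carry the same subtype structure, so the segment-to-gene projection
can be tested round-trip.

What the generator does **not** emulate: realistic TCGA marginal
distributions, count models for miRNA, correlated (block) missingness,
batch effects, or layers with conflicting subtype structure. Passing
recovery tests therefore demonstrate correctness of the machinery under
clean separable signal, not performance on real tumor cohorts.

## Problem sizes used in the test suite

The recovery contracts run the full pipeline on 60 samples × 3 layers with
100 consensus repetitions per K and both k_true ∈ {2, 3} over ten seeds;
smaller unit fixtures use 20–45 samples and 10–60 repetitions. These sizes
were chosen so the planted effect dominates sampling noise while the whole
suite stays desk-scale; repetitions and the gap-statistic B are
configuration, not constants, and scale up for production runs.

## Known limitations

- Samples missing from some layers are dropped (intersection policy); a
  union mode with zero-padded blocks is deliberately not the default
  because a zero row-block is not a valid one-hot membership.
- k-means ignores the configured distance (it is intrinsically
  Euclidean); the distance option applies to hierarchical and k-medoids.
- The k-medoids implementation is Voronoi iteration with a seeded random
  init, not PAM's full swap search; at consensus-resampling scale the
  difference washes out in M.
- Spearman distance recomputes rank correlations per subsample, which is
  the slowest of the distance options.
- ROC/AUC for hard cluster labels is the two-point ROC, AUC = (Sn+Sp)/2;
  the continuous alternative scores each sample by its mean consensus
  with the members of the class's clusters. Both are reported, as
  `AUC_labels` and `AUC_consensus`.
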
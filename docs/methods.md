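# Methods

## Occupancy model

Encapsulation is modelled as Poisson loading: each droplet independently
receives k ~ Poisson(λ) cells, λ being the mean over *all* droplets, empties
included. Conditioning on non-empty droplets gives the true multiplet rate
f_mult(λ) = 1 − λe^(−λ)/(1 − e^(−λ)). With D hashed samples pooled in equal
proportions and cells assigned to samples independently, a k-cell droplet is
single-sample with probability D^(−(k−1)); weighting by the zero-and-one
truncated Poisson mass gives the inter-sample multiplet fraction f_diff(λ, D),
and the hashing-observed rate is the product f_obs = f_mult · f_diff.

Assumptions worth stating plainly: cells are captured independently and
identically (no co-encapsulation bias from cell size, viability or adhesion),
samples contribute equal cell numbers, and hashing itself is error-free
(no tag spillover, no ambiguous droplets). Unequal sample proportions are
rejected with an explicit error rather than silently mis-estimated.

### Numerics

- `f_diff` uses the closed form
  1 − D e^(−λ)(e^(λ/D) − 1 − λ/D)/(1 − e^(−λ) − λe^(−λ)) for λ ≥ 1e−3.
  Below that, numerator and denominator are both O(λ²) and cancel
  catastrophically in floating point, so the series Σ_{k≥2} P(k)D^(−(k−1)) is
  summed term by term instead (terms are positive; the sum converges in a few
  terms). The two branches agree to ~1e−10 at the switch point. The tests
  additionally check the closed form against an independent truncated-series
  oracle (k ≤ 100) to 1e−10 on a (λ, D) grid.
- `solve_lambda` inverts f_obs(λ) by bisection: the upper bracket doubles
  from 1 until the model rate exceeds the target (the rate is strictly
  increasing in λ for D ≥ 2), then bisects to a residual of 1e−10 on f_obs.
- D = 1 is accepted by the forward functions (f_diff = 0) but rejected by the
  inverse: a single sample makes the observed rate identically zero and λ
  unidentifiable.
- The vendor heuristic is a configurable linear rule, default 0.8% per 1,000
  non-empty droplets for every chemistry; vendor tables differ slightly by
  chemistry version but the published tables are not reproduced here.

## Simulator

The generator draws k per droplet *including* empties and then discards k = 0,
mirroring the model's derivation, and assigns each cell a sample and a cell
type i.i.d. Defaults: λ = 0.7 (a moderately loaded hashed run, ~30% true
multiplets), D = 2 equal samples, two equally frequent cell types,
2,000 expected UMI per cell, negative-binomial dispersion 2 — values chosen
once as typical of hashed 10X-style experiments at desk scale.

Expression is the part the occupancy model says nothing about, so the choice
is ours and documented rather than inferred: all types share a log-normal
(σ = 1) baseline rate vector; each type's disjoint marker block (default 10
genes) is elevated 8-fold, so types differ exactly at marker positions.
Per-cell counts are negative binomial via gamma–Poisson mixing with the
type's rates scaled to the configured library size; `dispersion = inf` gives
the exact Poisson limit. A droplet's row is the element-wise sum of its
member cells' rows — the defining artefact of a multiplet.

What the simulator deliberately omits: ambient RNA, empty-droplet background,
barcode collisions, cell-size or viability effects on co-encapsulation,
hashing demultiplexing errors, batch effects. Passing tests therefore show
that the estimator and the evaluation protocols behave correctly under the
model's own assumptions; they do not show robustness to violations of those
assumptions in real data (the independence assumption in particular is known
to be optimistic).

Barcodes are fixed-width (14 nt) random A/C/G/T strings, regenerated on the
vanishingly rare collision. One global seed drives every substream.

## Detection evaluation

Scores are evaluated as rankings. AUPRC is average precision with tied scores
entering together (no interpolation); AUROC is the Mann–Whitney statistic
with ties counted half. Calling at an assumed rate takes k = round(rate·n)
(half-up) top-scored droplets, with boundary ties broken by lexicographic
droplet id for determinism — the convention is ours, chosen for
reproducibility. Intersection counts are exclusive (UpSet-style): each
droplet in the union contributes to exactly one membership pattern, so
pattern counts partition the union; the default report truncates to the 20
largest. Hashing labels are strictly binary here; ambiguous/negative
demultiplexing calls are out of scope.

On simulator output, a perfect multiplet score (the true cell count) reaches
AUROC 1 against true multiplet flags but not against hashing labels — the
lower-bound property of hashing, exercised as a test.

## Clustering evaluation

The pipeline is deliberately plain: CP10K + log1p, top-2,000 genes by
variance of the normalized values, z-scaling, 10 principal components, a
k = 20 nearest-neighbour graph, Louvain communities (igraph multilevel) at
resolution 1.0. All knobs are exposed; determinism comes from seeding both
the PCA and igraph's RNG. Labels are renumbered by decreasing cluster size.
A matrix whose rows are all identical short-circuits to a single cluster.

Version comparison follows the stratified-subsampling protocol: metrics are
computed on subsamples of a fixed size using the *original* labels (no
reclustering), 100 iterations by default, so dataset-size differences after
removal cannot drive the metrics. Per-cluster quotas use largest-remainder
apportionment (remainder ties to the larger cluster, then the smaller
label) — the stratification rule is ours, fixed for exactness. The default
subsample size is the largest multiple of 100 strictly below the smallest
version's droplet count; the rounding base of 100 is a package choice.

Rank aggregation: within each (dataset, metric) cell, versions are ranked by
median (descending for silhouette and Calinski–Harabasz, ascending for
Davies–Bouldin; median ties get mean ranks), IQRs (Q3 − Q1, linear
interpolation) are ranked ascending with the same tie convention, and the
combined score is performance rank + 0.1 × IQR rank, averaged over cells. A
silhouette-only aggregation is available because silhouette is the metric
most used on its own in practice. Ranks depend only on order, so the
aggregation is invariant to positive affine rescaling of any metric.

In the directional tests the Louvain resolution is lowered to 0.3 so that
each simulated transcriptional population maps to one community; at
resolution 1.0 the graph over-partitions small homogeneous blobs into
subclusters, which is normal Louvain behaviour but obscures the
silhouette contrast the test isolates.

## Differential-expression stability

The comparison protocol — 5% prevalence filter (≥ ceil(0.05·n) droplets with
a nonzero count), BH adjustment, significance at FDR < 0.05 and |log₂FC| >
0.5, Jaccard over significant sets, Spearman of log₂FC on the union — is the
contribution; the two-group test inside it is exchangeable. The built-in test
is a two-sided Wilcoxon rank-sum on CP10K + log1p values with log₂FC =
log₂((mean_B + 1)/(mean_A + 1)) on de-logged group means (first group =
reference); externally computed DE tables with `log2fc` and `significant`
columns can be ingested instead. Hurdle-model (MAST-style) coefficients are
not reproduced. Genes constant across both groups get p = 1 (the tie-degenerate
case of the rank-sum test). Removal for the second run only drops droplets;
normalization is per droplet, so no reprocessing is needed.

Jaccard is defined as 1 when both significant sets are empty; Spearman is
undefined (NaN) when the union has fewer than two genes.

## Problem sizes

Unit and property tests run on hand fixtures (≤ 20 elements) and simulations
of 0.6–1.6 thousand droplets with 300 genes; occupancy-recovery checks use
200,000 droplets (flags only, no expression), with agreement asserted within
3 Monte-Carlo standard errors obtained by the delta method on the numeric
inverse combined in quadrature with the binomial error of the realized
fraction. These sizes keep every statistical check well-powered while the
whole suite runs in well under a minute.

## Known limitations

- Equal sample proportions are assumed end to end; the unequal-sample
  generalization (per-sample cell counts) is a different estimator.
- The estimator propagates no uncertainty; confidence intervals would need a
  bootstrap over droplets.
- The expression model has no ambient RNA or batch structure, so detection
  AUROCs on simulated data are optimistic relative to real tools on real data.
- Louvain community structure on kNN graphs is resolution-sensitive;
  conclusions about cluster counts should not be read off the defaults.
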
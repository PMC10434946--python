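# Methods

## Problem

Single-cell expression analyses routinely reduce a cells × genes matrix to
2D (PCA preprocessing followed by t-SNE or UMAP) and read biology off the
picture: which cells are neighbors, how cell types relate, how mixed two
batches are, how separated clusters are. Each of those readings assumes a
geometric property — local neighborhoods, global type relationships, or
pairwise distances — is preserved by the reduction. This package measures
how badly each property is distorted, on data whose ground truth is fully
known, and provides Picasso, a shape-constrained embedding demonstrating
that the gross shape of a 2D embedding is an esthetic choice rather than a
data property.

## Spaces and preprocessing

The *ambient* space is the cells × genes matrix after highly-variable-gene
selection and log-normalization: each cell is scaled to a common total
(`target_sum`, default 1e4) and transformed with log(1 + x). Cells with
zero total counts cannot be normalized and are dropped with a warning. HVG
selection ranks genes by the variance of the log-normalized values — a
deliberately simple dispersion statistic, recorded in provenance — with
ties broken toward the lower gene index. *PCA-d* (default d = 50) is the
centered principal-component reduction of the ambient space; each
component's sign is fixed so its largest-magnitude loading is positive,
which makes scores reproducible across backends. Optional per-gene
z-scoring before PCA is exposed but off by default. 2D spaces are produced
by UMAP (umap-learn, default `n_neighbors` 15) or t-SNE (scikit-learn,
default perplexity 30) on either the PCA space ("PCA-50→UMAP") or the
ambient space directly; stochastic reducers run n = 3 replicates with
consecutive seeds by default. Every embedding records method, chain,
neighbor parameter, metric, seed and replicate, so it can be regenerated
from its provenance plus the input.

Distances are Euclidean (L2) by default — the native metric of the
reducers — and every statistic also accepts Manhattan (L1), which behaves
better in high dimension.

## Distortion statistics

**Local.** `knn_index` computes exact k nearest neighbors (default k = 30)
with ties broken by ascending cell index; `jaccard_neighbor_distance` is
1 − |A∩B|/|A∪B| between a cell's neighbor sets in two spaces (1.0 = no
overlap), averaged over cells and replicates.

**Global.** `type_distance_matrix` holds mean pairwise distances between
(off-diagonal) and within (diagonal) cell types; singleton types are
excluded with a warning. `type_ranking_correlation` ranks, for each type,
all other types by mean distance in each space and reports the Spearman
correlation (average-rank ties) of the two rankings. Spearman was chosen
because only a ranking correlation is called for; the choice is recorded in
run metadata. Replicate embeddings are aggregated as the mean/median of
per-replicate correlations, never by averaging rankings first; this choice
is flagged in output metadata.

**Distance.** `find_equidistant_groups` finds groups of 3–8 cells whose
pairwise distances all lie within a relative band ε of a target distance:
maximal cliques (Bron–Kerbosch with pivoting, via networkx) of the
distance-band graph, with "near"/"far" targets defaulting to the 5th/95th
percentiles of a subsampled pair pool. Maximal cliques larger than the size
cap contribute their lexicographically first members; output is sorted and
truncated deterministically. `max_min_ratio` is D/d, the largest over the
smallest pairwise distance within a group (1 for perfectly equidistant
points); `ratio_distortion` is its per-group fold change between spaces,
with a size-stratified summary to test growth of distortion with group
size. `jl_min_dimension` evaluates the Johnson–Lindenstrauss lower bound
8·ln(n)/ε² on the dimension needed to preserve all pairwise distances among
n points within relative error ε (10,000 points at ε = 0.2 → 1,842
dimensions).

**Applications.** `mixing_fractions` is the fraction of a cell's k
neighbors sharing its batch/condition label (1.0 = no mixing).
`knn_label_predict` holds out 30% of cells (stratified by label — this
prevents degenerate test classes on small data) and predicts each test
cell's label by majority vote of its 50 nearest training cells, ties broken
toward the label with smaller mean neighbor distance. `inter_intra_ks` is
the two-sample Kolmogorov–Smirnov statistic between pooled inter-type and
intra-type pairwise distances (pools subsampled to at most 10⁶ pairs with a
recorded seed), computed directly as the ECDF supremum.
`relative_contrast` is (Dmax − Dmin)/Dmin of the Lk distances from a query
point to all other points; queries are drawn at random (the per-query
scheme is flagged in metadata as a package choice), and duplicated queries
(Dmin = 0) are resampled with a warning. `hvg_subset_contrast_protocol`
draws 5 random subsets of 1,000 genes from the top 2,000 HVGs and returns
per-query log2(RC_L1/RC_L2), with the same queries used for both norms so
ratios are paired.

## Picasso

Picasso maps the input space (ambient log-normalized matrix by default;
PCA-50 optional) to 2D through a small MLP encoder (hidden widths 128 and
64, tanh units, linear 2D head) implemented in NumPy with hand-written
backpropagation. The minibatch objective is

    shape_weight · Chamfer(embedded batch, shape)
  + distance_weight · (1 − Pearson(ambient pair distances, embedded pair distances))

with both weights 1 by default. The shape term is the symmetric Chamfer
distance (sum of the two directed mean nearest-point distances) between the
embedded batch and the target shape cloud with *both* clouds normalized to
unit diameter — the shape once up front, the embedded batch inside the loss
with exact gradients through the centering and the diameter — so the
training objective is the same scale-free quantity the fit is scored by.
Chamfer is differentiable, point-order-free and directly expresses "fills
the shape". The distance term uses
within-minibatch pairs only (O(batch²), not O(n²)), matching how such
losses are trained in practice. There is no decoder/reconstruction term —
the distance term plays that role; whether the original formulation used
one in addition is not settled by the published description, so the default
omits it. Training uses Adam (base rate 3e-3, batch 256, 80 epochs by
default — settings chosen from pilot fits of the default mixture to the
elephant) with cosine decay of the learning rate, which measurably sharpens
the final shape fit; minibatch order and initialization are driven by the
config seed, so training is bit-reproducible. A non-finite loss raises a
training error with the offending configuration in the message.

`shape_fit_error` scores a fitted embedding as the symmetric Chamfer
distance after both clouds are normalized to unit diameter, so the score is
invariant to translation and uniform scaling and is 0 iff the point sets
coincide.

Limit behavior: with `distance_weight = 0` the embedding collapses onto the
shape regardless of data geometry; with `shape_weight = 0` Picasso is a
plain distance-preserving embedding. With small inputs note that the
batch-level Chamfer optimum differs slightly from the full-cloud optimum
(a batch cannot cover a much larger shape cloud exactly); full-batch
training removes this floor.

The target-shape library contains the four-complex-parameter Fourier
elephant (p₁ = 50−30i, p₂ = 18+8i, p₃ = 12−10i, p₄ = −14−60i, the optional
trunk-wiggle parameter omitted), a circle, a petal rose ("flower") and a
filled grid; arbitrary shapes load from CSV point lists.

## Synthetic data

`generate_mixture_counts` draws a cells × genes matrix of negative-binomial
counts: cell types are sampled from the configured proportions, each cell's
library size is log-normal (default median 5,000, log-sd 0.25), and counts
for a type-t cell are NB with shape `dispersion` (default 2.0) around the
library size apportioned by the type's normalized expression profile, so a
cell's expected total equals its library size. Per-type log-mean profiles
are a global Gaussian gene baseline (sd 2.0 in natural logs) plus a small
per-type deviation (sd 0.15), with 2.5% of genes per type upshifted by 1.5
log units as markers. The baseline spread was set so the simulated matrix
reproduces the summary statistics of real HVG-selected scRNA count
matrices — at the default scale about 64% zeros and gene means spanning
roughly four orders of magnitude; a narrower spread produces matrices far
denser than any real dataset. The default scale — 5,000 cells × 2,000
genes, 20 equally likely types — is the package's standard desk-scale
audit dataset. `add_batch_effect` applies i.i.d. per-gene Gaussian shifts
in log space (round(expm1(log1p(x) + s))) to one batch; zero shift or zero
affected fraction returns the input unchanged.

What the generator does *not* emulate: UMI chemistry, ambient RNA
contamination, doublets, gene–gene correlation beyond the type structure,
per-gene dispersions, or continuous (trajectory-like) populations. Passing
audits on this generator therefore demonstrate the distortion phenomena
under a clean discrete-type model; absolute metric values on real data will
differ even where the orderings are robust.

Geometric benchmarks: the Swiss-roll (t·cos t, h, t·sin t) with t starting
at π/2 and spanning a configurable number of turns, returned together with
its intrinsic (arc-length, height) coordinates; i.i.d. uniform hypercube
points; and regular (m−1)-simplices built by centering the m standard basis
vectors, rotating into their span, rescaling to a common pairwise distance
and zero-padding, with optional Gaussian jitter. At zero noise the simplex
and Swiss-roll identities hold to 1e-9 and are asserted in tests.

## Audit pipeline

`run_audit` drives dataset → chains → metrics from a single validated
config (YAML-loadable); every metric table row carries the property tag
(local/global/distance) the metric probes, and the report serializes as CSV
tables plus a JSON manifest of config, seeds and table hashes — two runs
from the same config produce identical hashes for deterministic stages.
Metric computations over (space, replicate) pairs are independent and
order-free. `mixing_experiment` builds a two-batch dataset at a
configurable shift and reports the K-S statistic between ambient and
embedded mixing distributions (the direction of distortion is not
constrained: embeddings both exaggerate and hide mixing).
`swissroll_experiment` scores neighbor scrambling of embedded rolls against
the known intrinsic plane across tightness and neighbor settings.

## Problem sizes and numerical choices

The standard audit dataset is 5,000 × 2,000 with 20 types; experiment
helpers default to 2,000 × 1,000 (mixing) and 600 3D points (Swiss-roll),
sizes at which every audit completes on a laptop-class single core.
Pairwise-distance pools are subsampled at 10⁶ pairs; kNN queries run in
1,024-row blocks against the full matrix, exactly, rather than through an
approximate index. All geometry is float64. Degenerate inputs are handled
explicitly: zero-total cells dropped with a warning, singleton types
excluded from type matrices, coincident points yield an infinite max/min
ratio with a warning, duplicated contrast queries are resampled, and kNN
ties resolve by ascending cell index so results are permutation-stable.

## Known limitations

Two behaviors of real scRNA-seq data are *not* reproduced by the
shared-dispersion mixture, and the corresponding audits report them as
such rather than papering over the difference. First, on this generator
PCA-50 denoises the count noise so well that its kNN label-prediction
accuracy slightly exceeds the ambient space's (≈ 1.000 vs ≈ 0.987), and
the discrete types remain perfectly separable even in 2D, so the
degradation of prediction accuracy down the reduction chain seen on real
tissue datasets does not emerge. Second, the L1-over-L2 relative-contrast
advantage that holds for real expression matrices (and for uniform
hypercube data, where this package's own tests confirm it) comes out
slightly negative (median log2 ratio ≈ −0.03) on the mixture: a single
shared NB dispersion lacks the heavy-tailed per-gene dispersion structure
that appears to drive the effect. Both are limitations of the count model,
not of the statistics.

t-SNE has no out-of-sample transform here (scikit-learn backend), so
transform-based experiments are UMAP-only. The equidistant-group search is
exact maximal-clique enumeration and is meant for desk-scale distance
matrices (≤ a few thousand cells within the band), not atlas-scale data.
Picasso makes no claim of reproducing the original shape-constrained
implementation weight-for-weight; it implements the published idea — an
encoder trained against a shape term plus an ambient-distance term — with
its own architecture and optimizer choices, and supports 2D target shapes
only.
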
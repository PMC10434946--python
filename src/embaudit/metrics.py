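"""Distortion statistics between a reference space and an embedded space.

Local structure is probed by the Jaccard dissimilarity of k-nearest-neighbor
sets; global structure by rank correlations of cell-type neighbor orderings
built from mean inter-type distances; distance structure by equidistant
cell groups (cliques in a distance-band graph), their max/min-ratio
inflation under embedding, and the Johnson–Lindenstrauss lower bound on the
dimension needed for bounded distance error. Additional application-level
statistics cover batch/condition mixing fractions, kNN label-prediction
accuracy, inter/intra-type distance separation (two-sample K-S), and the
relative-contrast ratio of Lk norms in high dimension.

All statistics accept either L1 (Manhattan) or L2 (Euclidean) distances.
Expensive O(n²) pair pools are subsampled at a configurable cap with a
recorded seed.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .containers import (
    EmbeddingMatrix,
    EquidistantGroupSet,
    ExpressionMatrix,
    NeighborIndex,
    TypeDistanceMatrix,
    ValidationError,
)

__all__ = [
    "pairwise_dists",
    "knn_index",
    "jaccard_neighbor_distance",
    "type_distance_matrix",
    "type_ranking_correlation",
    "find_equidistant_groups",
    "near_far_targets",
    "max_min_ratio",
    "ratio_distortion",
    "mixing_fractions",
    "knn_label_predict",
    "inter_intra_ks",
    "inter_intra_correlation",
    "relative_contrast",
    "hvg_subset_contrast_protocol",
    "jl_min_dimension",
]

_SK_METRIC = {"L1": "manhattan", "L2": "euclidean"}


def _points_of(data) -> np.ndarray:
    if isinstance(data, ExpressionMatrix):
        return data.dense()
    if isinstance(data, EmbeddingMatrix):
        return data.coords
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError("expected an n × d coordinate array")
    return arr


def _ids_of(data, n: int) -> np.ndarray:
    if isinstance(data, (ExpressionMatrix, EmbeddingMatrix)):
        return data.cell_ids
    return np.array([f"cell_{i:05d}" for i in range(n)], dtype=object)


def pairwise_dists(X, Y=None, metric: str = "L2") -> np.ndarray:
    """Dense pairwise distance matrix under the L1 or L2 norm."""
    from sklearn.metrics import pairwise_distances

    if metric not in _SK_METRIC:
        raise ValidationError(f"metric must be 'L1' or 'L2', got {metric!r}")
    X = _points_of(X)
    Y = X if Y is None else _points_of(Y)
    D = pairwise_distances(X, Y, metric=_SK_METRIC[metric])
    return np.maximum(D, 0.0)


# ---------------------------------------------------------------------------
# Local structure
# ---------------------------------------------------------------------------

def knn_index(points, k: int, metric: str = "L2", *,
              dists: Optional[np.ndarray] = None,
              source_space: str = "", chunk: int = 1024) -> NeighborIndex:
    """Exact k nearest neighbors per point, ties broken by ascending index.

    ``dists`` may supply a precomputed square distance matrix to avoid
    recomputation when several statistics share one space.
    """
    X = _points_of(points)
    n = X.shape[0]
    if not (1 <= k < n):
        raise ValidationError(f"k={k} must satisfy 1 ≤ k < n_points={n}")
    idx = np.empty((n, k), dtype=np.int64)
    nd = np.empty((n, k), dtype=np.float64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = dists[start:stop] if dists is not None \
            else pairwise_dists(X[start:stop], X, metric)
        block = np.array(block, dtype=np.float64, copy=True)
        block[np.arange(start, stop) - start, np.arange(start, stop)] = np.inf
        order = np.argsort(block, axis=1, kind="stable")[:, :k]
        idx[start:stop] = order
        nd[start:stop] = np.take_along_axis(block, order, axis=1)
    return NeighborIndex(k=k, metric=metric, neighbor_idx=idx, neighbor_dists=nd,
                         cell_ids=_ids_of(points, n), source_space=source_space)


def jaccard_neighbor_distance(idxA: NeighborIndex, idxB: NeighborIndex) -> np.ndarray:
    """Per-cell Jaccard dissimilarity 1 − |A∩B| / |A∪B| of k-NN sets.

    1.0 denotes no overlap between a cell's neighborhoods in the two spaces.
    """
    if idxA.k != idxB.k:
        raise ValidationError("neighbor indices must use the same k")
    if idxA.n_cells != idxB.n_cells or np.any(idxA.cell_ids != idxB.cell_ids):
        raise ValidationError("neighbor indices cover different cell sets")
    k = idxA.k
    scores = np.empty(idxA.n_cells)
    for i in range(idxA.n_cells):
        inter = len(frozenset(idxA.neighbor_idx[i]) & frozenset(idxB.neighbor_idx[i]))
        scores[i] = 1.0 - inter / (2 * k - inter)
    return scores


# ---------------------------------------------------------------------------
# Global structure
# ---------------------------------------------------------------------------

def type_distance_matrix(points, labels, metric: str = "L2", *,
                         dists: Optional[np.ndarray] = None) -> TypeDistanceMatrix:
    """Mean pairwise distances between (and within) cell types.

    Off-diagonal (s, t): mean over all cross-type pairs. Diagonal (t, t):
    mean over within-type pairs excluding self-pairs. Types with a single
    cell are excluded with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    X = _points_of(points)
    if labels.shape[0] != X.shape[0]:
        raise ValidationError("labels must cover all cells")
    uniq, counts = np.unique(labels, return_counts=True)
    singletons = uniq[counts < 2]
    if singletons.size:
        warnings.warn(f"excluding singleton type(s): {list(singletons)}")
        uniq = uniq[counts >= 2]
    if uniq.size < 2:
        raise ValidationError("need at least 2 types with ≥ 2 cells")
    groups = [np.flatnonzero(labels == t) for t in uniq]
    t = uniq.size
    values = np.zeros((t, t))
    for a in range(t):
        for b in range(a, t):
            if dists is not None:
                block = dists[np.ix_(groups[a], groups[b])]
            else:
                block = pairwise_dists(X[groups[a]], X[groups[b]], metric)
            if a == b:
                n = block.shape[0]
                values[a, a] = block.sum() / (n * (n - 1))  # off-diagonal mean
            else:
                values[a, b] = values[b, a] = block.mean()
    return TypeDistanceMatrix(labels=uniq, values=values, metric=metric)


def type_ranking_correlation(ref: TypeDistanceMatrix,
                             test: TypeDistanceMatrix) -> np.ndarray:
    """Per-type Spearman correlation of cell-type neighbor rankings.

    For each type, the other types are ranked by mean inter-type distance in
    each space; the returned value is the rank correlation (average-rank tie
    handling) between the two orderings.
    """
    if ref.n_types != test.n_types or np.any(ref.labels != test.labels):
        raise ValidationError("type distance matrices cover different types")
    t = ref.n_types
    if t < 3:
        raise ValidationError("ranking correlation needs at least 3 types")
    out = np.empty(t)
    for i in range(t):
        others = np.arange(t) != i
        rho = scipy.stats.spearmanr(ref.values[i, others], test.values[i, others])
        out[i] = rho.statistic
    return out


# ---------------------------------------------------------------------------
# Distance structure
# ---------------------------------------------------------------------------

def near_far_targets(dists: np.ndarray, q_near: float = 0.05, q_far: float = 0.95,
                     max_pairs: int = 1_000_000, seed: int = 0) -> tuple[float, float]:
    """(near, far) target distances: low/high percentiles of the pair pool."""
    n = dists.shape[0]
    iu = np.triu_indices(n, k=1)
    pool = dists[iu]
    if pool.size > max_pairs:
        rng = np.random.default_rng(seed)
        pool = rng.choice(pool, size=max_pairs, replace=False)
    return (float(np.quantile(pool, q_near)), float(np.quantile(pool, q_far)))


def find_equidistant_groups(
    dists: np.ndarray,
    target_distance: float,
    epsilon: float,
    size_min: int = 3,
    size_max: int = 8,
    limit: Optional[int] = None,
    regime: str = "near",
    node_cap: Optional[int] = None,
    source_space: str = "",
) -> EquidistantGroupSet:
    """Maximal groups of cells whose pairwise distances all lie in one band.

    Builds the graph whose edges are pairs with distance in
    [target·(1−ε), target·(1+ε)] and enumerates its maximal cliques
    (Bron–Kerbosch with pivoting). Maximal cliques larger than ``size_max``
    contribute their lexicographically first ``size_max`` members; cliques
    smaller than ``size_min`` are dropped. Results are sorted by (size,
    member tuple) and truncated to ``limit``, making the output
    deterministic for identical inputs. An empty band yields an empty set.
    """
    import networkx as nx

    dists = np.asarray(dists, dtype=np.float64)
    if dists.ndim != 2 or dists.shape[0] != dists.shape[1]:
        raise ValidationError("find_equidistant_groups expects a square distance matrix")
    if target_distance <= 0:
        raise ValidationError("target_distance must be positive")
    if not (0 < epsilon < 0.5):
        raise ValidationError("epsilon must lie in (0, 0.5)")
    if not (2 <= size_min <= size_max):
        raise ValidationError("need 2 ≤ size_min ≤ size_max")
    lo = target_distance * (1.0 - epsilon)
    hi = target_distance * (1.0 + epsilon)
    band = (dists >= lo) & (dists <= hi)
    np.fill_diagonal(band, False)
    band &= band.T  # guard asymmetric numerical noise in the input
    deg = band.sum(axis=1)
    nodes = np.flatnonzero(deg >= size_min - 1)
    if node_cap is not None and nodes.size > node_cap:
        nodes = nodes[:node_cap]
    groups: set[tuple[int, ...]] = set()
    if nodes.size:
        sub = band[np.ix_(nodes, nodes)]
        g = nx.from_numpy_array(sub)
        for clique in nx.find_cliques(g):
            if len(clique) < size_min:
                continue
            members = tuple(sorted(int(nodes[v]) for v in clique))[:size_max]
            groups.add(members)
    ordered = sorted(groups, key=lambda m: (len(m), m))
    if limit is not None:
        ordered = ordered[:limit]
    return EquidistantGroupSet(groups=ordered, target_distance=target_distance,
                               tolerance_band=epsilon, regime=regime,
                               source_space=source_space)


def max_min_ratio(points, group: Sequence[int], metric: str = "L2") -> float:
    """Ratio D/d of the largest to smallest pairwise distance in a group.

    Equals 1 for perfectly equidistant points. Coincident points (d = 0)
    yield an infinite ratio with a warning.
    """
    group = np.asarray(sorted(set(int(i) for i in group)), dtype=int)
    if group.size < 2:
        raise ValidationError("a group needs at least 2 members")
    X = _points_of(points)[group]
    D = pairwise_dists(X, metric=metric)
    iu = np.triu_indices(group.size, k=1)
    vals = D[iu]
    dmin, dmax = float(vals.min()), float(vals.max())
    if dmin == 0.0:
        warnings.warn("coincident points in group: max/min ratio is infinite")
        return float("inf")
    return dmax / dmin


def ratio_distortion(groups: EquidistantGroupSet, spaceA, spaceB,
                     metric: str = "L2") -> tuple[np.ndarray, "pd.DataFrame"]:
    """Per-group fold change of max/min ratio between two spaces.

    Returns (fold changes: ratio in spaceB / ratio in spaceA, one per group)
    plus a size-stratified summary table (median and mean fold per group
    size) used to test growth of distortion with group size. Fold changes
    are scale-free in either space.
    """
    import pandas as pd

    XA, XB = _points_of(spaceA), _points_of(spaceB)
    if XA.shape[0] != XB.shape[0]:
        raise ValidationError("spaces must share cells")
    folds = np.empty(len(groups))
    sizes = groups.sizes()
    for i, g in enumerate(groups.groups):
        if max(g) >= XB.shape[0]:
            raise ValidationError("group member missing in target space")
        ra = max_min_ratio(XA, g, metric)
        rb = max_min_ratio(XB, g, metric)
        folds[i] = rb / ra
    df = pd.DataFrame({"size": sizes, "fold": folds})
    summary = df.groupby("size")["fold"].agg(["count", "median", "mean"]).reset_index()
    return folds, summary


def jl_min_dimension(n: int, eps: float) -> tuple[float, int]:
    """Johnson–Lindenstrauss lower bound 8·ln(n)/ε² on the target dimension.

    Returns (real-valued bound, its integer floor): the minimum number of
    dimensions guaranteeing preservation of all pairwise distances among n
    points within relative error ε under a random linear embedding.
    """
    if n < 2:
        raise ValidationError("n must be at least 2")
    if not (0 < eps < 1):
        raise ValidationError("eps must lie in (0, 1)")
    bound = 8.0 * np.log(n) / (eps * eps)
    return float(bound), int(np.floor(bound))


# ---------------------------------------------------------------------------
# Application-level statistics
# ---------------------------------------------------------------------------

def mixing_fractions(idx: NeighborIndex, labels,
                     restrict_label=None) -> np.ndarray:
    """Fraction of each cell's k neighbors sharing the cell's label.

    1.0 = no mixing. With ``restrict_label`` the distribution is restricted
    to the cells carrying that label.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != idx.n_cells:
        raise ValidationError("labels must cover all cells")
    if any(l is None or (isinstance(l, float) and np.isnan(l)) for l in labels):
        raise ValidationError("unlabeled cell")
    same = labels[idx.neighbor_idx] == labels[:, None]
    frac = same.mean(axis=1)
    if restrict_label is not None:
        frac = frac[labels == restrict_label]
    return frac


def knn_label_predict(points, labels, test_fraction: float = 0.3, k: int = 50,
                      metric: str = "L2", seed: int = 0) -> float:
    """kNN majority-vote label prediction accuracy on a stratified split.

    A ``test_fraction`` of cells (stratified by label) is held out and each
    test cell receives the majority label of its k nearest training cells;
    vote ties are broken toward the label with smaller mean neighbor
    distance. If some label has fewer than k training cells, k is reduced
    with a warning.
    """
    from sklearn.model_selection import train_test_split

    labels = np.asarray(labels, dtype=object)
    X = _points_of(points)
    if labels.shape[0] != X.shape[0]:
        raise ValidationError("labels must cover all cells")
    if not (0 < test_fraction < 1):
        raise ValidationError("test_fraction must lie in (0, 1)")
    idx = np.arange(X.shape[0])
    train, test = train_test_split(idx, test_size=test_fraction,
                                   stratify=labels, random_state=seed)
    train = np.sort(train)
    test = np.sort(test)
    if k >= train.size:
        raise ValidationError(f"k={k} must be smaller than the training size")
    _, class_counts = np.unique(labels[train], return_counts=True)
    min_class = int(class_counts.min())
    if min_class < k:
        warnings.warn(f"label with only {min_class} training cells; reducing "
                      f"k from {k} to {min_class}")
        k = min_class
    correct = 0
    chunk = 512
    for start in range(0, test.size, chunk):
        sel = test[start:start + chunk]
        D = pairwise_dists(X[sel], X[train], metric)
        order = np.argsort(D, axis=1, kind="stable")[:, :k]
        for r in range(sel.size):
            neigh = order[r]
            votes = labels[train[neigh]]
            dists_r = D[r, neigh]
            uniq, counts = np.unique(votes, return_counts=True)
            top = counts.max()
            tied = uniq[counts == top]
            if tied.size == 1:
                winner = tied[0]
            else:  # smaller mean neighbor distance wins
                means = [dists_r[votes == lab].mean() for lab in tied]
                winner = tied[int(np.argmin(means))]
            correct += winner == labels[sel[r]]
    return correct / test.size


def _pair_pools(X_or_D, labels, metric: str, max_pairs: int, seed: int,
                dists_given: bool) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=object)
    n = labels.shape[0]
    rng = np.random.default_rng(seed)
    total = n * (n - 1) // 2
    if total <= max_pairs:
        iu = np.triu_indices(n, k=1)
        ii, jj = iu
    else:
        ii = rng.integers(0, n, size=int(max_pairs * 1.2))
        jj = rng.integers(0, n, size=int(max_pairs * 1.2))
        keep = ii < jj
        ii, jj = ii[keep][:max_pairs], jj[keep][:max_pairs]
    if dists_given:
        d = np.asarray(X_or_D)[ii, jj]
    else:
        X = _points_of(X_or_D)
        if metric == "L2":
            d = np.linalg.norm(X[ii] - X[jj], axis=1)
        else:
            d = np.abs(X[ii] - X[jj]).sum(axis=1)
    same = labels[ii] == labels[jj]
    return d[~same], d[same]


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample K-S statistic: supremum of the ECDF difference."""
    a = np.sort(np.asarray(a, dtype=np.float64))
    b = np.sort(np.asarray(b, dtype=np.float64))
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(fa - fb).max())


def inter_intra_ks(points_or_dists, labels, metric: str = "L2",
                   max_pairs: int = 1_000_000, seed: int = 0,
                   dists_given: bool = False) -> tuple[float, np.ndarray, np.ndarray]:
    """Separation of inter- vs intra-type pairwise distance distributions.

    Pools all inter-type and all intra-type pairwise distances (subsampled
    to ``max_pairs`` with the recorded seed) and returns the two-sample
    Kolmogorov–Smirnov statistic together with the two pools. Higher values
    denote greater type separation.
    """
    labels = np.asarray(labels, dtype=object)
    if np.unique(labels).size < 2:
        raise ValidationError("need at least 2 types")
    inter, intra = _pair_pools(points_or_dists, labels, metric, max_pairs,
                               seed, dists_given)
    if inter.size < 2 or intra.size < 2:
        raise ValidationError("need at least 2 distances in each pool")
    return _ks_statistic(inter, intra), inter, intra


def inter_intra_correlation(test_space, ref_space, labels, metric: str = "L2",
                            *, dists_test: Optional[np.ndarray] = None,
                            dists_ref: Optional[np.ndarray] = None
                            ) -> tuple[float, float]:
    """Pearson correlation of inter- and intra-type distances across spaces.

    ``inter``: correlation of the off-diagonal mean inter-type distances of
    the two spaces (global relationships between clusters). ``intra``:
    correlation of the within-type mean distances (the spread of each type).
    """
    tdm_test = type_distance_matrix(test_space, labels, metric, dists=dists_test)
    tdm_ref = type_distance_matrix(ref_space, labels, metric, dists=dists_ref)
    if tdm_test.n_types < 3:
        raise ValidationError("need at least 3 types")
    inter = scipy.stats.pearsonr(tdm_ref.off_diagonal(), tdm_test.off_diagonal())
    intra = scipy.stats.pearsonr(tdm_ref.diagonal(), tdm_test.diagonal())
    return float(inter.statistic), float(intra.statistic)


def relative_contrast(points, query_count: int = 50, norm_order: int = 2,
                      seed: int = 0) -> np.ndarray:
    """Relative contrast (Dmax − Dmin)/Dmin of Lk distances from query points.

    Measures how well the Lk norm delineates proximity: higher contrast
    means the farthest point is meaningfully farther than the nearest.
    Queries are drawn at random without replacement; a query whose nearest
    other point is at distance 0 (a duplicate) is flagged and resampled.
    """
    if norm_order not in (1, 2):
        raise ValidationError("norm_order must be 1 or 2")
    X = _points_of(points)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 points")
    if query_count < 1:
        raise ValidationError("query_count must be positive")
    rng = np.random.default_rng(seed)
    candidates = rng.permutation(n)
    out = []
    for q in candidates:
        if len(out) == query_count:
            break
        diff = X - X[q]
        d = np.abs(diff).sum(axis=1) if norm_order == 1 \
            else np.linalg.norm(diff, axis=1)
        d[q] = np.nan
        dmin = np.nanmin(d)
        if dmin == 0.0:
            warnings.warn(f"query {q} duplicates another point; resampled")
            continue
        out.append((np.nanmax(d) - dmin) / dmin)
    if len(out) < query_count:
        raise ValidationError("could not find enough non-duplicated queries")
    return np.asarray(out)


def hvg_subset_contrast_protocol(matrix: ExpressionMatrix, n_subsets: int = 5,
                                 subset_size: int = 1000, pool_size: int = 2000,
                                 query_count: int = 50, seed: int = 0) -> np.ndarray:
    """log2(RC_L1 / RC_L2) over random HVG subsets in the ambient gene space.

    Selects the top ``pool_size`` highly variable genes, draws ``n_subsets``
    random subsets of ``subset_size`` genes, and for each subset computes the
    relative contrast of the L1 and L2 norms over the same random queries,
    returning the per-query log2 ratios (length n_subsets × query_count).
    Positive values mean L1 delineates proximity better than L2.
    """
    from .harness import lognormalize, select_hvg

    if subset_size > pool_size:
        raise ValidationError("subset_size cannot exceed pool_size")
    if matrix.n_genes < pool_size:
        raise ValidationError(f"need at least pool_size={pool_size} genes")
    if matrix.layer == "counts":
        matrix = lognormalize(matrix)
    pool = select_hvg(matrix, pool_size)
    X = pool.dense()
    rng = np.random.default_rng(seed)
    # one query draw shared by all subsets and both norms, so every log2
    # ratio is paired and identical gene subsets give identical values
    qseed = int(rng.integers(0, 2**31 - 1))
    ratios = []
    for s in range(n_subsets):
        genes = np.sort(rng.choice(pool_size, size=subset_size, replace=False))
        sub = X[:, genes]
        rc1 = relative_contrast(sub, query_count, norm_order=1, seed=qseed)
        rc2 = relative_contrast(sub, query_count, norm_order=2, seed=qseed)
        ratios.append(np.log2(rc1 / rc2))
    return np.concatenate(ratios)
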
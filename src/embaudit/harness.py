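"""Standardized preprocessing and reduction chains.

Mirrors common single-cell practice: counts → log-normalize (per-cell total
scaled to ``target_sum`` then log1p) → highly-variable-gene selection →
PCA to a few dozen dimensions → nonlinear reduction to 2D (UMAP or t-SNE).
Chains are named ("ambient", "pca-50", "pca-50-umap", "umap", ...) and every
produced :class:`EmbeddingMatrix` carries full provenance — method,
preprocessing chain, neighbor parameter or perplexity, metric, seed and
replicate index — so any embedding can be regenerated from its record.

The nonlinear reducers are delegated: UMAP to umap-learn, t-SNE to
scikit-learn. Out-of-sample transform is available for UMAP only.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .containers import (
    EmbeddingMatrix,
    ExpressionMatrix,
    ValidationError,
    provenance,
)

__all__ = [
    "lognormalize",
    "select_hvg",
    "run_pca",
    "run_nonlinear_2d",
    "fit_nonlinear_2d",
    "transform_new_points",
    "EmbedConfig",
    "pipeline_embed",
    "parameter_sweep",
    "DEFAULT_TARGET_SUM",
    "DEFAULT_PCA_D",
]

DEFAULT_TARGET_SUM = 1e4
DEFAULT_PCA_D = 50
DEFAULT_UMAP_NEIGHBORS = 15
DEFAULT_TSNE_PERPLEXITY = 30

_METRIC_NAMES = {"L1": "manhattan", "L2": "euclidean"}


def _check_metric(metric: str) -> str:
    if metric not in _METRIC_NAMES:
        raise ValidationError(f"metric must be 'L1' or 'L2', got {metric!r}")
    return _METRIC_NAMES[metric]


def _coords(data) -> np.ndarray:
    """Dense coordinate view of an ExpressionMatrix, EmbeddingMatrix or array."""
    if isinstance(data, ExpressionMatrix):
        return data.dense()
    if isinstance(data, EmbeddingMatrix):
        return data.coords
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError("expected a 2D array of coordinates")
    return arr


def _cell_ids(data, n: int) -> np.ndarray:
    if isinstance(data, (ExpressionMatrix, EmbeddingMatrix)):
        return data.cell_ids
    return np.array([f"cell_{i:05d}" for i in range(n)], dtype=object)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def lognormalize(counts: ExpressionMatrix,
                 target_sum: float = DEFAULT_TARGET_SUM) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    Cells with zero total counts cannot be normalized; they are dropped with
    a warning.
    """
    if counts.layer != "counts":
        raise ValidationError("lognormalize expects the counts layer")
    if target_sum <= 0:
        raise ValidationError("target_sum must be positive")
    values = counts.values
    totals = np.asarray(values.sum(axis=1)).ravel()
    keep = totals > 0
    if not np.all(keep):
        warnings.warn(f"excluding {int((~keep).sum())} zero-total cell(s)")
        values = values[keep]
        totals = totals[keep]
    scale = target_sum / totals
    if sp.issparse(values):
        normed = sp.diags(scale) @ values.astype(np.float64)
        normed = normed.log1p().tocsr()
    else:
        normed = np.log1p(np.asarray(values, dtype=np.float64) * scale[:, None])
    return ExpressionMatrix(normed, counts.cell_ids[keep], counts.gene_ids,
                            layer="lognorm")


def select_hvg(matrix: ExpressionMatrix, n_top: int) -> ExpressionMatrix:
    """Keep the ``n_top`` genes with highest variance, preserving gene order.

    The dispersion statistic is the variance of the (log-normalized) values;
    ties are broken toward the lower gene index.
    """
    if n_top <= 0:
        raise ValidationError("n_top must be positive")
    if n_top > matrix.n_genes:
        raise ValidationError(f"n_top={n_top} exceeds {matrix.n_genes} genes")
    if n_top == matrix.n_genes:
        return matrix
    dense = matrix.dense()
    var = dense.var(axis=0)
    order = np.argsort(-var, kind="stable")  # stable → lower index wins ties
    chosen = np.sort(order[:n_top])  # preserve input gene order
    return matrix.subset_genes(chosen)


def run_pca(matrix, d: int, seed: int = 0) -> EmbeddingMatrix:
    """Centered principal-component scores with a fixed sign convention.

    Each component's sign is chosen so that its largest-magnitude loading is
    positive, making scores reproducible across backends up to numerical
    noise.
    """
    from sklearn.decomposition import PCA

    X = _coords(matrix)
    n, g = X.shape
    if not (1 <= d <= min(n, g)):
        raise ValidationError(f"d={d} must satisfy 1 ≤ d ≤ min(n_cells, n_genes)")
    pca = PCA(n_components=d, svd_solver="auto", random_state=seed)
    scores = pca.fit_transform(X)
    for j in range(d):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    prov = provenance("pca", d=d, seed=seed,
                      chain=getattr(matrix, "layer", None) or "array")
    return EmbeddingMatrix(scores, _cell_ids(matrix, n), prov)


# ---------------------------------------------------------------------------
# Nonlinear 2D reduction
# ---------------------------------------------------------------------------

def fit_nonlinear_2d(
    data,
    method: str,
    neighbor_param: int | None = None,
    metric: str = "L2",
    seed: int = 0,
):
    """Fit a 2D reducer and return (fitted model, EmbeddingMatrix)."""
    X = _coords(data)
    n = X.shape[0]
    sk_metric = _check_metric(metric)
    if method == "umap":
        try:
            import umap
        except ImportError as exc:  # pragma: no cover - environment guard
            raise ValidationError("umap backend unavailable") from exc
        k = neighbor_param if neighbor_param is not None else DEFAULT_UMAP_NEIGHBORS
        if not (1 < k < n):
            raise ValidationError(f"neighbor_param={k} must be in (1, n_cells)")
        model = umap.UMAP(n_components=2, n_neighbors=k, metric=sk_metric,
                          random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = model.fit_transform(X)
        param_name = "n_neighbors"
    elif method == "tsne":
        from sklearn.manifold import TSNE

        k = neighbor_param if neighbor_param is not None else DEFAULT_TSNE_PERPLEXITY
        if not (1 < k < n):
            raise ValidationError(f"perplexity={k} must be in (1, n_cells)")
        model = TSNE(n_components=2, perplexity=k, metric=sk_metric,
                     random_state=seed, init="pca")
        coords = model.fit_transform(np.ascontiguousarray(X))
        param_name = "perplexity"
    else:
        raise ValidationError(f"unknown nonlinear method {method!r}")
    prov = provenance(method, **{param_name: k}, metric=metric, seed=seed,
                      chain=_chain_of(data))
    emb = EmbeddingMatrix(np.asarray(coords, dtype=np.float64),
                          _cell_ids(data, n), prov)
    return model, emb


def run_nonlinear_2d(data, method: str, neighbor_param: int | None = None,
                     metric: str = "L2", seed: int = 0) -> EmbeddingMatrix:
    """2D UMAP/t-SNE embedding with pinned seed and recorded provenance."""
    _, emb = fit_nonlinear_2d(data, method, neighbor_param, metric, seed)
    return emb


def transform_new_points(model, new_points) -> EmbeddingMatrix:
    """Map new points into a fitted 2D space (UMAP only)."""
    if not hasattr(model, "transform"):
        raise ValidationError(
            f"{type(model).__name__} does not support out-of-sample transform")
    X = _coords(new_points)
    expected = getattr(model, "_raw_data", None)
    if expected is not None and X.shape[1] != expected.shape[1]:
        raise ValidationError(
            f"new points have {X.shape[1]} features, reducer was fitted on "
            f"{expected.shape[1]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.transform(X)
    prov = provenance("umap-transform")
    return EmbeddingMatrix(np.asarray(coords, dtype=np.float64),
                           _cell_ids(new_points, X.shape[0]), prov)


def _chain_of(data) -> str:
    if isinstance(data, ExpressionMatrix):
        return f"ambient-{data.layer}"
    if isinstance(data, EmbeddingMatrix):
        m = data.provenance.get("method", "array")
        d = data.provenance.get("d", data.d)
        return f"{m}-{d}"
    return "array"


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

@dataclass
class EmbedConfig:
    """Configuration of pipeline_embed.

    ``chains`` names the spaces to produce: "ambient" (identity on the
    log-normalized matrix), "pca-<d>", "pca-<d>-umap"/"pca-<d>-tsne"
    (PCA preprocessing then 2D), or "umap"/"tsne" (direct 2D from ambient).
    Stochastic 2D chains are replicated ``n_replicates`` times with seeds
    seed, seed+1, ....
    """

    chains: Sequence[str] = ("ambient", "pca-50", "pca-50-umap")
    target_sum: float = DEFAULT_TARGET_SUM
    n_hvg: int | None = None
    scale_genes: bool = False  # optional z-scoring before PCA, off by default
    neighbor_param: int | None = None
    metric: str = "L2"
    n_replicates: int = 3
    seed: int = 0


def _parse_chain(name: str) -> tuple[str, int | None, str | None]:
    """Return (kind, pca_d, nonlinear_method) for a chain name."""
    parts = name.lower().split("-")
    if parts == ["ambient"]:
        return "ambient", None, None
    if parts[0] == "pca":
        if len(parts) == 2 and parts[1].isdigit():
            return "pca", int(parts[1]), None
        if len(parts) == 3 and parts[1].isdigit() and parts[2] in ("umap", "tsne"):
            return "pca2d", int(parts[1]), parts[2]
    if parts in (["umap"], ["tsne"]):
        return "direct2d", None, parts[0]
    raise ValidationError(f"unknown chain name {name!r}")


def pipeline_embed(counts: ExpressionMatrix, config: EmbedConfig) -> dict:
    """Run the requested preprocessing/reduction chains.

    Returns a dict mapping chain name to a list of EmbeddingMatrix
    (deterministic chains yield one entry; stochastic 2D chains yield
    ``n_replicates`` entries with consecutive seeds). Cell order is
    identical across every produced space.
    """
    if not config.chains:
        raise ValidationError("at least one chain required")
    parsed = [(_parse_chain(name), name) for name in config.chains]

    ambient = lognormalize(counts, config.target_sum) if counts.layer == "counts" \
        else counts
    if config.n_hvg is not None:
        ambient = select_hvg(ambient, config.n_hvg)
    X = ambient.dense()
    if config.scale_genes:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
        ambient = ExpressionMatrix(X, ambient.cell_ids, ambient.gene_ids,
                                   layer="scaled")

    pca_cache: dict[int, EmbeddingMatrix] = {}

    def pca_d(d: int) -> EmbeddingMatrix:
        if d not in pca_cache:
            pca_cache[d] = run_pca(ambient, d, seed=config.seed)
        return pca_cache[d]

    out: dict[str, list[EmbeddingMatrix]] = {}
    for (kind, d, method), name in parsed:
        if kind == "ambient":
            prov = provenance("identity", chain="ambient", layer=ambient.layer)
            out[name] = [EmbeddingMatrix(X.copy(), ambient.cell_ids, prov)]
        elif kind == "pca":
            out[name] = [pca_d(d)]
        else:
            source = pca_d(d) if kind == "pca2d" else ambient
            reps = []
            for r in range(config.n_replicates):
                emb = run_nonlinear_2d(source, method, config.neighbor_param,
                                       config.metric, seed=config.seed + r)
                emb.provenance["replicate"] = r
                emb.provenance["chain"] = name
                reps.append(emb)
            out[name] = reps
    return out


def parameter_sweep(data, method: str, neighbor_params: Sequence[int],
                    metric: str = "L2", seed: int = 0) -> list[EmbeddingMatrix]:
    """One 2D embedding per neighbor setting, same seed and input."""
    if not len(neighbor_params):
        raise ValidationError("neighbor_params must be non-empty")
    return [run_nonlinear_2d(data, method, int(p), metric, seed)
            for p in neighbor_params]
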
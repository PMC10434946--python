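"""Picasso: shape-constrained 2D embedding.

Picasso embeds a dataset into an arbitrary 2D target shape while preserving
ambient cell-to-cell distance structure about as well as t-SNE/UMAP,
demonstrating that the apparent "shape" of a 2D embedding is an arbitrary
property. The encoder is a small multilayer perceptron from the input space
(ambient log-normalized matrix by default, or a PCA reduction) to 2D,
trained by minibatch gradient descent (Adam) on a two-term objective:

* shape term — symmetric Chamfer distance between the embedded minibatch
  point cloud and the target shape point cloud (the shape is centered and
  scaled to unit diameter once, up front);
* distance term — 1 − Pearson correlation between ambient and embedded
  pairwise distances over within-minibatch pairs.

The implementation is pure NumPy with hand-written backpropagation, so a
fixed seed yields bit-identical training: parameter init and minibatch
order are both driven by the config seed.

``shape_weight = 0`` reduces to a pure distance-preserving embedding;
``distance_weight = 0`` collapses the embedding onto the shape regardless
of data geometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .containers import (
    EmbeddingMatrix,
    ExpressionMatrix,
    Shape2D,
    ValidationError,
    provenance,
)

__all__ = ["PicassoConfig", "TrainingError", "fit_picasso", "shape_fit_error",
           "normalize_cloud"]


class TrainingError(RuntimeError):
    """Raised when the Picasso loss diverges (non-finite)."""


@dataclass
class PicassoConfig:
    shape_weight: float = 1.0
    distance_weight: float = 1.0
    encoder_layout: Sequence[int] = (128, 64)
    epochs: int = 80
    batch_size: int = 256
    learning_rate: float = 3e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_weight < 0 or self.distance_weight < 0:
            raise ValidationError("weights must be nonnegative")
        if self.shape_weight + self.distance_weight == 0:
            raise ValidationError("at least one loss weight must be positive")
        if self.epochs < 1:
            raise ValidationError("epochs must be at least 1")
        if self.batch_size < 8:
            raise ValidationError("batch_size must be at least 8")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")


def normalize_cloud(points: np.ndarray) -> np.ndarray:
    """Center a 2D point cloud and scale it to unit diameter."""
    pts = np.asarray(points, dtype=np.float64)
    pts = pts - pts.mean(axis=0)
    diam = pdist(pts).max() if pts.shape[0] <= 4000 else _approx_diameter(pts)
    if diam <= 0:
        raise ValidationError("degenerate point cloud (zero diameter)")
    return pts / diam


def _approx_diameter(pts: np.ndarray) -> float:
    # exact diameter of a planar cloud via its convex hull
    from scipy.spatial import ConvexHull

    hull = pts[ConvexHull(pts).vertices]
    return pdist(hull).max()


def _chamfer(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Symmetric Chamfer distance a↔b and its gradient w.r.t. a.

    Defined as mean_i min_j ||a_i − b_j|| + mean_j min_i ||b_j − a_i||.
    """
    eps = 1e-12  # guards the gradient denominator only; distances are exact
    diff = a[:, None, :] - b[None, :, :]  # |a| × |b| × 2
    d = np.sqrt((diff * diff).sum(axis=2))
    ja = d.argmin(axis=1)  # nearest shape point per embedded point
    ib = d.argmin(axis=0)  # nearest embedded point per shape point
    na, nb = a.shape[0], b.shape[0]
    a2b = d[np.arange(na), ja].mean()
    b2a = d[ib, np.arange(nb)].mean()
    grad = (a - b[ja]) / ((d[np.arange(na), ja][:, None] + eps) * na)
    gb = (a[ib] - b) / ((d[ib, np.arange(nb)][:, None] + eps) * nb)
    np.add.at(grad, ib, gb)
    return float(a2b + b2a), grad


def _normalized_chamfer(y: np.ndarray, s: np.ndarray) -> tuple[float, np.ndarray]:
    """Chamfer between the unit-diameter-normalized cloud y and shape s.

    s must already be centered and unit-diameter. Returns the loss and its
    gradient w.r.t. the raw y, backpropagated through the centering and the
    diameter (a subgradient at the max-distance pair).
    """
    from scipy.spatial.distance import cdist

    eps = 1e-12
    yc = y - y.mean(axis=0)
    D2 = cdist(yc, yc, "sqeuclidean")
    p, q = np.unravel_index(np.argmax(D2), D2.shape)
    diam = np.sqrt(D2[p, q]) + eps
    yn = yc / diam
    ch, gn = _chamfer(yn, s)
    grad = (gn - gn.mean(axis=0)) / diam
    c = float((gn * yn).sum())  # dL/d(diam) = -c/diam
    u = (yc[p] - yc[q]) / diam
    grad[p] -= c * u / diam
    grad[q] += c * u / diam
    return ch, grad


def _distance_corr_loss(y: np.ndarray, v: np.ndarray,
                        ii: np.ndarray, jj: np.ndarray
                        ) -> tuple[float, np.ndarray]:
    """1 − Pearson(embedded pair distances, ambient pair distances) + grad."""
    eps = 1e-12
    delta = y[ii] - y[jj]
    u = np.sqrt((delta * delta).sum(axis=1) + eps)
    ut = u - u.mean()
    vt = v - v.mean()
    su = np.sqrt((ut * ut).sum()) + eps
    sv = np.sqrt((vt * vt).sum()) + eps
    r = float((ut * vt).sum() / (su * sv))
    # centering terms vanish exactly because ũ, ṽ are mean-free
    dr_du = vt / (su * sv) - r * ut / (su * su)
    dL_du = -dr_du
    g_pair = (dL_du / u)[:, None] * delta
    grad = np.zeros_like(y)
    np.add.at(grad, ii, g_pair)
    np.add.at(grad, jj, -g_pair)
    return 1.0 - r, grad


class _MLP:
    """Tiny dense network with tanh hidden units and a linear 2D head."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        acts = [x]
        h = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = z if i == len(self.W) - 1 else np.tanh(z)
            acts.append(h)
        return h, acts

    def backward(self, acts: list, grad_out: np.ndarray) -> list:
        grads = []
        g = grad_out
        for i in reversed(range(len(self.W))):
            h_in, h_out = acts[i], acts[i + 1]
            if i != len(self.W) - 1:
                g = g * (1.0 - h_out * h_out)  # tanh'
            gW = h_in.T @ g
            gb = g.sum(axis=0)
            grads.append((gW, gb))
            g = g @ self.W[i].T
        return grads[::-1]

    def params(self):
        return self.W + self.b


class _Adam:
    def __init__(self, shapes, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list, grads: list) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def fit_picasso(data, shape: Shape2D, config: PicassoConfig | None = None
                ) -> EmbeddingMatrix:
    """Fit cells to an arbitrary 2D shape while preserving ambient distances.

    ``data`` may be an :class:`ExpressionMatrix` (ambient log-normalized
    space; the default input), an :class:`EmbeddingMatrix` (e.g. PCA-50),
    or a plain array. Returns the 2D coordinates with loss history recorded
    in provenance.
    """
    config = config or PicassoConfig()
    if isinstance(data, ExpressionMatrix):
        X = data.dense()
        cell_ids = data.cell_ids
        source = f"ambient-{data.layer}"
    elif isinstance(data, EmbeddingMatrix):
        X = data.coords
        cell_ids = data.cell_ids
        source = data.provenance.get("method", "embedding")
    else:
        X = np.asarray(data, dtype=np.float64)
        cell_ids = np.array([f"cell_{i:05d}" for i in range(X.shape[0])],
                            dtype=object)
        source = "array"
    n = X.shape[0]
    if n < 100:
        raise ValidationError("Picasso needs at least 100 cells")
    S = normalize_cloud(shape.points)

    # standardized copy conditions the network input; ambient pair distances
    # for the correlation target are taken from the raw input space
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    rng = np.random.default_rng(config.seed)
    net = _MLP([X.shape[1], *config.encoder_layout, 2], rng)
    opt = _Adam([p.shape for p in net.params()], config.learning_rate)

    b = min(config.batch_size, n)
    ii, jj = np.triu_indices(b, k=1)
    history = []
    base_lr = config.learning_rate
    for epoch in range(config.epochs):
        # cosine decay to a tenth of the base rate sharpens the final fit
        opt.lr = base_lr * (0.55 + 0.45 * np.cos(np.pi * epoch / config.epochs))
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n - b + 1, b):
            sel = perm[start:start + b]
            xb = Xs[sel]
            y, acts = net.forward(xb)
            loss = 0.0
            gy = np.zeros_like(y)
            if config.shape_weight > 0:
                ch, gch = _normalized_chamfer(y, S)
                loss += config.shape_weight * ch
                gy += config.shape_weight * gch
            if config.distance_weight > 0:
                # BLAS-backed batch distance matrix, then pair extraction
                from scipy.spatial.distance import cdist

                Db = cdist(X[sel], X[sel])
                v = Db[ii, jj]
                dl, gdl = _distance_corr_loss(y, v, ii, jj)
                loss += config.distance_weight * dl
                gy += config.distance_weight * gdl
            if not np.isfinite(loss):
                raise TrainingError(
                    f"loss diverged at epoch {epoch}: {loss!r} "
                    f"(lr={config.learning_rate}, batch={b})")
            layer_grads = net.backward(acts, gy)
            flat = [g for gW, _ in layer_grads for g in (gW,)] + \
                   [gb for _, gb in layer_grads]
            opt.step(net.params(), flat)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))

    coords, _ = net.forward(Xs)
    prov = provenance("picasso", shape=shape.name, seed=config.seed,
                      shape_weight=config.shape_weight,
                      distance_weight=config.distance_weight,
                      epochs=config.epochs, batch_size=b,
                      learning_rate=config.learning_rate,
                      encoder_layout=list(config.encoder_layout),
                      input=source, final_loss=history[-1],
                      loss_history=[round(h, 6) for h in history])
    return EmbeddingMatrix(coords, cell_ids, prov)


def shape_fit_error(embedding, shape: Shape2D) -> float:
    """Symmetric Chamfer distance between normalized clouds.

    Both the embedded point cloud and the shape are centered and scaled to
    unit diameter first, so the error is invariant to translation and
    uniform scaling; it is 0 iff the two point sets coincide as sets.
    """
    if isinstance(embedding, EmbeddingMatrix):
        pts = embedding.coords
    else:
        pts = np.asarray(embedding, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("shape_fit_error requires a 2D embedding")
    a = normalize_cloud(pts)
    s = normalize_cloud(shape.points)
    err, _ = _chamfer(a, s)
    return err
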
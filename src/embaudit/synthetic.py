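"""Synthetic inputs with known ground truth.

Two families of generators feed the audit:

* an scRNA-seq-like count simulator — negative-binomial counts over
  type-specific log-mean profiles with log-normal library-size variation,
  many discrete cell types, and an optional additive (log-space) batch
  effect; and
* geometric benchmarks — the Swiss-roll manifold, uniform hypercube points,
  regular simplices (perfectly equidistant point groups), and a library of
  2D target shapes including the four-parameter Fourier "elephant" curve.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .containers import (
    AnnotationTable,
    ExpressionMatrix,
    Shape2D,
    ValidationError,
)

__all__ = [
    "MixtureSpec",
    "default_mixture_spec",
    "generate_mixture_counts",
    "add_batch_effect",
    "generate_swiss_roll",
    "swiss_roll_arc_length",
    "generate_uniform_points",
    "generate_equidistant_simplex",
    "elephant_shape",
    "circle_shape",
    "flower_shape",
    "grid_shape",
    "SHAPE_LIBRARY",
]


# ---------------------------------------------------------------------------
# Count mixture
# ---------------------------------------------------------------------------

@dataclass
class MixtureSpec:
    """Parameters of the negative-binomial cell-type mixture.

    ``mean_log_expression`` holds one log-mean profile per type (n_types ×
    n_genes). Each cell draws a type from ``type_proportions``, a library
    size from LogNormal(``library_size_log_mean``, ``library_size_log_sd``),
    and gene counts NB-distributed around the library size apportioned by
    the type's softmax expression profile. ``dispersion`` is the NB shape
    (smaller = more overdispersed).
    """

    n_cells: int
    n_genes: int
    n_types: int
    type_proportions: np.ndarray
    mean_log_expression: np.ndarray
    dispersion: float = 2.0
    library_size_log_mean: float = float(np.log(5000.0))
    library_size_log_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValidationError("n_cells and n_genes must be positive")
        if self.n_types < 1:
            raise ValidationError("need at least one type")
        self.type_proportions = np.asarray(self.type_proportions, dtype=np.float64)
        if self.type_proportions.shape != (self.n_types,):
            raise ValidationError("type_proportions length must equal n_types")
        if abs(self.type_proportions.sum() - 1.0) > 1e-9:
            raise ValidationError("type_proportions must sum to 1")
        if self.type_proportions.min() < 0:
            raise ValidationError("type_proportions must be nonnegative")
        self.mean_log_expression = np.asarray(self.mean_log_expression, dtype=np.float64)
        if self.mean_log_expression.shape != (self.n_types, self.n_genes):
            raise ValidationError("mean_log_expression must be n_types × n_genes")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")


def default_mixture_spec(
    n_cells: int = 5000,
    n_genes: int = 2000,
    n_types: int = 20,
    *,
    dispersion: float = 2.0,
    library_size_log_mean: float = float(np.log(5000.0)),
    library_size_log_sd: float = 0.25,
    baseline_sd: float = 2.0,
    type_sd: float = 0.15,
    marker_fraction: float = 0.025,
    marker_shift: float = 1.5,
    seed: int = 0,
) -> MixtureSpec:
    """Build a MixtureSpec with a marker-gene type structure.

    Per-type log-means are a global Gaussian gene baseline plus a small
    per-type deviation; a ``marker_fraction`` of genes per type is upshifted
    by ``marker_shift`` (natural-log units), giving each type a discrete
    marker signature, the geometry discrete-type analyses assume. Defaults
    correspond to the audit's standard desk-scale dataset: 5,000 cells ×
    2,000 genes in 20 equally likely types.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11CE]))
    baseline = rng.normal(0.0, baseline_sd, size=n_genes)
    means = baseline[None, :] + rng.normal(0.0, type_sd, size=(n_types, n_genes))
    n_markers = max(1, int(round(marker_fraction * n_genes)))
    for t in range(n_types):
        markers = rng.choice(n_genes, size=n_markers, replace=False)
        means[t, markers] += marker_shift
    props = np.full(n_types, 1.0 / n_types)
    return MixtureSpec(
        n_cells=n_cells,
        n_genes=n_genes,
        n_types=n_types,
        type_proportions=props,
        mean_log_expression=means,
        dispersion=dispersion,
        library_size_log_mean=library_size_log_mean,
        library_size_log_sd=library_size_log_sd,
        seed=seed,
    )


def generate_mixture_counts(spec: MixtureSpec) -> tuple[ExpressionMatrix, AnnotationTable]:
    """Draw a cells × genes integer count matrix plus type labels.

    Counts for a cell of type t are NB(shape=dispersion) around
    ``lib_c · softmax(mean_log_expression[t])`` where ``lib_c`` is the cell's
    log-normal library-size draw, so the expected total count of a cell
    equals its library size.
    """
    rng = np.random.default_rng(spec.seed)
    types = rng.choice(spec.n_types, size=spec.n_cells, p=spec.type_proportions)
    lib = rng.lognormal(spec.library_size_log_mean, spec.library_size_log_sd,
                        size=spec.n_cells)
    expr = np.exp(spec.mean_log_expression)
    profiles = expr / expr.sum(axis=1, keepdims=True)  # per-type gene fractions
    mean = lib[:, None] * profiles[types]
    theta = spec.dispersion
    p = theta / (theta + mean)
    counts = rng.negative_binomial(theta, p).astype(np.int64)
    cell_ids = np.array([f"cell_{i:05d}" for i in range(spec.n_cells)], dtype=object)
    gene_ids = np.array([f"gene_{j:04d}" for j in range(spec.n_genes)], dtype=object)
    matrix = ExpressionMatrix(sp.csr_matrix(counts), cell_ids, gene_ids, layer="counts")
    labels = np.array([f"type_{t:02d}" for t in types], dtype=object)
    ann = AnnotationTable.from_labels(
        cell_ids,
        type=labels,
        condition=np.full(spec.n_cells, "ctrl", dtype=object),
        batch=np.full(spec.n_cells, "batch0", dtype=object),
    )
    return matrix, ann


def add_batch_effect(
    matrix: ExpressionMatrix,
    annotations: AnnotationTable,
    shift_sd: float,
    affected_fraction: float = 1.0,
    seed: int = 0,
    batch_column: str = "batch",
) -> ExpressionMatrix:
    """Apply per-gene additive log-space shifts to one batch of cells.

    The highest-sorted batch level is shifted: for an affected gene g the
    counts x of shifted cells become round(expm1(log1p(x) + s_g)) with
    s_g ~ N(0, shift_sd). ``shift_sd = 0`` or ``affected_fraction = 0``
    return the input unchanged.
    """
    if shift_sd < 0:
        raise ValidationError("shift_sd must be nonnegative")
    if not (0.0 <= affected_fraction <= 1.0):
        raise ValidationError("affected_fraction must be a probability")
    batches = annotations.aligned_to(matrix.cell_ids).labels(batch_column)
    levels = sorted(set(batches))
    if len(levels) < 2:
        raise ValidationError("batch effect requires at least two batch levels")
    if shift_sd == 0 or affected_fraction == 0:
        return matrix
    rng = np.random.default_rng(seed)
    n_affected = int(round(affected_fraction * matrix.n_genes))
    genes = np.sort(rng.choice(matrix.n_genes, size=n_affected, replace=False))
    shifts = rng.normal(0.0, shift_sd, size=n_affected)
    target = np.asarray(batches) == levels[-1]
    dense = matrix.dense()
    block = dense[np.ix_(target, genes)]
    block = np.rint(np.expm1(np.log1p(block) + shifts[None, :]))
    dense[np.ix_(target, genes)] = np.maximum(block, 0.0)
    values = sp.csr_matrix(dense.astype(np.int64)) if sp.issparse(matrix.values) \
        else dense.astype(np.int64)
    return ExpressionMatrix(values, matrix.cell_ids, matrix.gene_ids, layer=matrix.layer)


# ---------------------------------------------------------------------------
# Geometric benchmarks
# ---------------------------------------------------------------------------

def swiss_roll_arc_length(t: np.ndarray) -> np.ndarray:
    """Arc length of the spiral (t·cos t, t·sin t) from 0 to t."""
    t = np.asarray(t, dtype=np.float64)
    return 0.5 * (t * np.sqrt(1.0 + t * t) + np.arcsinh(t))


def generate_swiss_roll(
    n_points: int,
    turns: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    height: float = 21.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a 3D Swiss-roll plus its intrinsic 2D coordinates.

    Points satisfy (t·cos t, h, t·sin t) + N(0, noise_sd) with the roll
    parameter t spanning ``turns`` full revolutions starting at t = π/2 and
    h uniform on [0, height]. The returned intrinsic coordinates are
    (arc length along the spiral, h), the flat ground truth the roll was
    "rolled up" from.
    """
    if n_points < 10:
        raise ValidationError("need at least 10 points")
    if turns <= 0:
        raise ValidationError("turns must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    t0 = 0.5 * np.pi
    t = t0 + 2.0 * np.pi * turns * rng.random(n_points)
    h = height * rng.random(n_points)
    points = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    if noise_sd > 0:
        points = points + rng.normal(0.0, noise_sd, size=points.shape)
    intrinsic = np.column_stack([swiss_roll_arc_length(t), h])
    return points, intrinsic


def generate_uniform_points(n: int, d: int, seed: int = 0) -> np.ndarray:
    """i.i.d. uniform[0, 1]^d points, reproducible by seed."""
    if n <= 0 or d <= 0:
        raise ValidationError("n and d must be positive")
    rng = np.random.default_rng(seed)
    return rng.random((n, d))


def generate_equidistant_simplex(
    m: int,
    d: Optional[int] = None,
    scale: float = 1.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """m points forming a regular (m−1)-simplex with side ``scale`` in R^d.

    The construction centers the m standard basis vectors of R^m (pairwise
    distance √2), rotates them into their (m−1)-dimensional span, rescales,
    and zero-pads to d dimensions; optional i.i.d. Gaussian jitter follows.
    """
    if m < 2:
        raise ValidationError("a simplex needs at least 2 vertices")
    if d is None:
        d = m - 1
    if d < m - 1:
        raise ValidationError(f"d={d} cannot hold a regular {m}-vertex simplex")
    if scale <= 0:
        raise ValidationError("scale must be positive")
    if jitter_sd < 0:
        raise ValidationError("jitter_sd must be nonnegative")
    verts = np.eye(m) - 1.0 / m  # centered; rank m-1
    # rotate into the span: right singular vectors give coordinates
    u, s, _ = np.linalg.svd(verts, full_matrices=False)
    coords = (u * s)[:, : m - 1]  # m × (m-1), pairwise distance √2
    coords = coords * (scale / np.sqrt(2.0))
    out = np.zeros((m, d))
    out[:, : m - 1] = coords
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, jitter_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# 2D target shapes
# ---------------------------------------------------------------------------

# Four complex parameters of the Fourier elephant (Mayer, Khairy & Howard,
# Am. J. Phys. 78, 648, 2010); the fifth "wiggling trunk" parameter is
# omitted.
_ELEPHANT_P = (50 - 30j, 18 + 8j, 12 - 10j, -14 - 60j)


def _fourier(t: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for k, c in enumerate(coeffs):
        out += c.real * np.cos(k * t) + c.imag * np.sin(k * t)
    return out


def elephant_shape(n_points: int = 400) -> Shape2D:
    """The "von Neumann elephant": a closed curve from 4 complex parameters.

    Sampled uniformly in the curve parameter over [0, 2π)."""
    if n_points < 16:
        raise ValidationError("need at least 16 points to trace the elephant")
    p1, p2, p3, p4 = _ELEPHANT_P
    cx = np.zeros(6, dtype=complex)
    cy = np.zeros(6, dtype=complex)
    cx[1] = p1.real * 1j
    cx[2] = p2.real * 1j
    cx[3] = p3.real
    cx[5] = p4.real
    cy[1] = p4.imag + p1.imag * 1j
    cy[2] = p2.imag * 1j
    cy[3] = p3.imag * 1j
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    x = _fourier(t, cx)
    y = _fourier(t, cy)
    # orient trunk-down, head-up as conventionally drawn
    return Shape2D("elephant", np.column_stack([y, -x]), closed=True)


def circle_shape(n_points: int = 200, radius: float = 1.0) -> Shape2D:
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return Shape2D("circle", radius * np.column_stack([np.cos(t), np.sin(t)]), closed=True)


def flower_shape(n_points: int = 400, petals: int = 6, amplitude: float = 0.4) -> Shape2D:
    """A petal rose curve r(θ) = 1 + amplitude·cos(petals·θ)."""
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = 1.0 + amplitude * np.cos(petals * t)
    return Shape2D("flower", np.column_stack([r * np.cos(t), r * np.sin(t)]), closed=True)


def grid_shape(n_side: int = 15, extent: float = 1.0) -> Shape2D:
    """A filled square grid of points (not a curve)."""
    g = np.linspace(-extent, extent, n_side)
    xx, yy = np.meshgrid(g, g)
    return Shape2D("grid", np.column_stack([xx.ravel(), yy.ravel()]), closed=False)


SHAPE_LIBRARY = {
    "elephant": elephant_shape,
    "circle": circle_shape,
    "flower": flower_shape,
    "grid": grid_shape,
}
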
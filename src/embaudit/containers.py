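"""Shared in-memory containers for the audit toolkit.

All downstream analysis is phrased in terms of four light containers:

* :class:`ExpressionMatrix` — a cells × genes matrix (raw counts or
  log-normalized values) with identifier lists and a layer tag.
* :class:`AnnotationTable` — per-cell categorical labels (type, condition,
  batch) backed by a :class:`pandas.DataFrame`.
* :class:`EmbeddingMatrix` — cells × d coordinates with full provenance of
  the reduction that produced them.
* :class:`NeighborIndex` — per-cell ordered k-nearest-neighbor lists with
  distances, tagged by metric and source space.

Containers validate their invariants on construction and stay deliberately
thin; heavy lifting lives in the analysis modules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "AnnotationTable",
    "EmbeddingMatrix",
    "NeighborIndex",
    "TypeDistanceMatrix",
    "EquidistantGroupSet",
    "Shape2D",
    "DistortionReport",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a container or operation precondition is violated."""


def _as_str_array(ids: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1:
        raise ValidationError(f"{what} must be one-dimensional")
    if len(set(arr)) != arr.size:
        raise ValidationError(f"duplicate {what}")
    return arr


@dataclass
class ExpressionMatrix:
    """Cells × genes numeric matrix (sparse-capable) with identifiers.

    ``layer`` is one of ``counts`` (nonnegative integers), ``lognorm``
    (log1p of library-size-normalized counts) or ``scaled``.
    """

    values: Any  # ndarray or scipy sparse, cells × genes
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        if self.layer not in ("counts", "lognorm", "scaled"):
            raise ValidationError(f"unknown layer {self.layer!r}")
        shape = self.values.shape
        if shape != (self.cell_ids.size, self.gene_ids.size):
            raise ValidationError(
                f"values shape {shape} does not match {self.cell_ids.size} "
                f"cells × {self.gene_ids.size} genes"
            )
        if self.layer == "counts":
            data = self.values.data if sp.issparse(self.values) else self.values
            if data.size and np.asarray(data).min() < 0:
                raise ValidationError("counts layer must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def dense(self) -> np.ndarray:
        """Return values as a dense float64 array."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return np.asarray(self.values, dtype=np.float64)

    def subset_genes(self, mask_or_idx: np.ndarray) -> "ExpressionMatrix":
        vals = self.values.tocsc()[:, mask_or_idx].tocsr() if sp.issparse(self.values) \
            else self.values[:, mask_or_idx]
        return ExpressionMatrix(vals, self.cell_ids, self.gene_ids[mask_or_idx], self.layer)

    def subset_cells(self, mask_or_idx: np.ndarray) -> "ExpressionMatrix":
        vals = self.values[mask_or_idx]
        return ExpressionMatrix(vals, self.cell_ids[mask_or_idx], self.gene_ids, self.layer)


@dataclass
class AnnotationTable:
    """Per-cell categorical labels: type, condition, batch."""

    table: pd.DataFrame  # index = cell_id; columns subset of {type, condition, batch}

    def __post_init__(self) -> None:
        if not isinstance(self.table, pd.DataFrame):
            raise ValidationError("AnnotationTable needs a DataFrame")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate cell ids in annotation table")

    @classmethod
    def from_labels(cls, cell_ids: Sequence[str], *, type=None, condition=None,
                    batch=None) -> "AnnotationTable":
        df = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
        if type is not None:
            df["type"] = np.asarray(type, dtype=object)
        if condition is not None:
            df["condition"] = np.asarray(condition, dtype=object)
        if batch is not None:
            df["batch"] = np.asarray(batch, dtype=object)
        return cls(df)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.asarray(self.table.index, dtype=object)

    def labels(self, column: str) -> np.ndarray:
        if column not in self.table.columns:
            raise ValidationError(f"annotation column {column!r} missing")
        col = self.table[column]
        if col.isna().any():
            raise ValidationError(f"unlabeled cells in column {column!r}")
        return np.asarray(col, dtype=object)

    def aligned_to(self, cell_ids: Sequence[str]) -> "AnnotationTable":
        return AnnotationTable(self.table.loc[list(cell_ids)])


@dataclass
class EmbeddingMatrix:
    """Cells × d real coordinates plus the provenance of their reduction."""

    coords: np.ndarray
    cell_ids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValidationError("coords must be a cells × d matrix with d ≥ 1")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        if self.coords.shape[0] != self.cell_ids.size:
            raise ValidationError("coords rows must match cell_ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite embedding coordinates")

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class NeighborIndex:
    """Exact k-nearest-neighbor lists (self excluded), ordered by distance."""

    k: int
    metric: str  # "L1" | "L2"
    neighbor_idx: np.ndarray  # n × k integer positions into cell_ids
    neighbor_dists: np.ndarray  # n × k nonnegative, nondecreasing rows
    cell_ids: np.ndarray
    source_space: str = ""

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        n = self.cell_ids.size
        if self.neighbor_idx.shape != (n, self.k):
            raise ValidationError("neighbor_idx shape mismatch")
        if self.neighbor_dists.shape != (n, self.k):
            raise ValidationError("neighbor_dists shape mismatch")
        rows = np.arange(n)[:, None]
        if np.any(self.neighbor_idx == rows):
            raise ValidationError("self appears in its own neighbor list")
        if np.any(np.diff(self.neighbor_dists, axis=1) < -1e-9):
            raise ValidationError("neighbor distances must be nondecreasing")
        if self.neighbor_dists.size and self.neighbor_dists.min() < 0:
            raise ValidationError("negative neighbor distance")

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    def neighbor_sets(self) -> list:
        return [frozenset(row) for row in self.neighbor_idx]


@dataclass
class TypeDistanceMatrix:
    """Mean pairwise inter-type distances; diagonal = mean intra-type."""

    labels: np.ndarray  # ordered type names
    values: np.ndarray  # symmetric, nonnegative
    metric: str = "L2"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        t = self.labels.size
        if self.values.shape != (t, t):
            raise ValidationError("type distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("type distance matrix must be symmetric")
        if self.values.size and self.values.min() < -1e-12:
            raise ValidationError("type distances must be nonnegative")

    @property
    def n_types(self) -> int:
        return self.labels.size

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n_types, k=1)
        return self.values[iu]

    def diagonal(self) -> np.ndarray:
        return np.diag(self.values).copy()


@dataclass
class EquidistantGroupSet:
    """Groups of cells whose pairwise distances all sit in one narrow band."""

    groups: list  # list of tuples of integer cell positions
    target_distance: float
    tolerance_band: float  # relative half-width ε
    regime: str = "near"  # "near" | "far"
    source_space: str = ""

    def __post_init__(self) -> None:
        if self.target_distance <= 0:
            raise ValidationError("target_distance must be positive")
        if not (0 < self.tolerance_band < 0.5):
            raise ValidationError("tolerance band must lie in (0, 0.5)")
        self.groups = [tuple(sorted(int(i) for i in g)) for g in self.groups]

    def __len__(self) -> int:
        return len(self.groups)

    def sizes(self) -> np.ndarray:
        return np.array([len(g) for g in self.groups], dtype=int)


@dataclass
class Shape2D:
    """A named 2D point cloud, optionally a closed curve."""

    name: str
    points: np.ndarray  # n × 2
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("shape points must be n × 2")
        if self.points.shape[0] < 3:
            raise ValidationError("a shape needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("non-finite shape coordinates")
        if self.diameter() <= 0:
            raise ValidationError("shape has zero diameter")

    def diameter(self) -> float:
        lo = self.points.min(axis=0)
        hi = self.points.max(axis=0)
        # bbox diagonal bounds the diameter within √2; exact diameter below
        from scipy.spatial.distance import pdist

        if self.points.shape[0] > 2000:
            return float(np.linalg.norm(hi - lo))
        return float(pdist(self.points).max())


@dataclass
class DistortionReport:
    """Named metric tables plus the configuration that produced them."""

    tables: dict = field(default_factory=dict)  # name -> DataFrame
    config: dict = field(default_factory=dict)

    def add(self, name: str, table: pd.DataFrame) -> None:
        self.tables[name] = table

    def manifest(self) -> dict:
        import hashlib

        hashes = {}
        for name in sorted(self.tables):
            csv = self.tables[name].to_csv(float_format="%.10g").encode()
            hashes[name] = hashlib.sha256(csv).hexdigest()
        return {"config": self.config, "table_hashes": hashes}

    def write(self, outdir) -> None:
        """Serialize as a directory of CSV tables plus a JSON manifest."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv", float_format="%.10g")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2, default=str)


def provenance(method: str, **kwargs: Any) -> dict:
    """Build a provenance record for an EmbeddingMatrix."""
    rec = {"method": method}
    rec.update({k: v for k, v in kwargs.items() if v is not None})
    return rec
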
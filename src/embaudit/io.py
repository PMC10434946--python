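"""Readers and writers for the standard on-disk formats.

Counts travel as Matrix Market (.mtx) with sidecar one-column gene/cell ID
files; labels as TSV (cell_id, type, condition, batch); embeddings as CSV
(cell_id, dim1..dimd) with a JSON provenance sidecar; shapes and point sets
as CSV. An HDF5 single-cell container (.h5ad) is read through anndata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    AnnotationTable,
    EmbeddingMatrix,
    ExpressionMatrix,
    Shape2D,
    ValidationError,
)

__all__ = [
    "write_mtx", "read_mtx",
    "write_annotations", "read_annotations",
    "write_embedding", "read_embedding",
    "write_shape", "read_shape",
    "read_h5ad",
]


def write_mtx(matrix: ExpressionMatrix, prefix) -> None:
    """Write counts to <prefix>.mtx plus <prefix>.cells.txt / .genes.txt."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    values = matrix.values if sp.issparse(matrix.values) else sp.csr_matrix(matrix.values)
    scipy.io.mmwrite(str(prefix) + ".mtx", values)
    Path(str(prefix) + ".cells.txt").write_text("\n".join(matrix.cell_ids) + "\n")
    Path(str(prefix) + ".genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")


def read_mtx(prefix, layer: str = "counts") -> ExpressionMatrix:
    prefix = Path(prefix)
    values = sp.csr_matrix(scipy.io.mmread(str(prefix) + ".mtx"))
    cells = Path(str(prefix) + ".cells.txt").read_text().split()
    genes = Path(str(prefix) + ".genes.txt").read_text().split()
    if layer == "counts":
        values = values.astype(np.int64)
    return ExpressionMatrix(values, np.array(cells, dtype=object),
                            np.array(genes, dtype=object), layer=layer)


def write_annotations(ann: AnnotationTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ann.table.rename_axis("cell_id").to_csv(path, sep="\t")


def read_annotations(path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", index_col="cell_id", dtype=str)
    return AnnotationTable(df)


def write_embedding(embedding: EmbeddingMatrix, path) -> None:
    """CSV with header cell_id, dim1..dimd plus a .json provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [f"dim{i + 1}" for i in range(embedding.d)]
    df = pd.DataFrame(embedding.coords, columns=cols)
    df.insert(0, "cell_id", embedding.cell_ids)
    df.to_csv(path, index=False)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(embedding.provenance, fh, indent=2, default=str)


def read_embedding(path) -> EmbeddingMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise ValidationError("embedding CSV must have a cell_id column")
    coords = df.drop(columns=["cell_id"]).to_numpy(dtype=np.float64)
    sidecar = path.with_suffix(path.suffix + ".json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return EmbeddingMatrix(coords, df["cell_id"].astype(str).to_numpy(dtype=object), prov)


def write_shape(shape: Shape2D, path) -> None:
    df = pd.DataFrame(shape.points, columns=["x", "y"])
    df.to_csv(path, index=False)


def read_shape(path, name: str | None = None, closed: bool = True) -> Shape2D:
    df = pd.read_csv(path)
    return Shape2D(name or Path(path).stem, df[["x", "y"]].to_numpy(), closed=closed)


def read_h5ad(path, layer: str = "counts") -> tuple[ExpressionMatrix, AnnotationTable]:
    """Read a .h5ad single-cell container: X plus obs label columns."""
    import anndata

    adata = anndata.read_h5ad(path)
    values = adata.X
    if sp.issparse(values):
        values = sp.csr_matrix(values)
    else:
        values = np.asarray(values)
    if layer == "counts":
        values = values.astype(np.int64)
    cells = np.asarray(adata.obs_names, dtype=object)
    genes = np.asarray(adata.var_names, dtype=object)
    matrix = ExpressionMatrix(values, cells, genes, layer=layer)
    kw = {}
    for col in ("type", "condition", "batch"):
        if col in adata.obs.columns:
            kw[col] = np.asarray(adata.obs[col].astype(str), dtype=object)
    ann = AnnotationTable.from_labels(cells, **kw)
    return matrix, ann
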
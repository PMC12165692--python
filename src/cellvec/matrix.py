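"""Expression-matrix container and file IO.

The central in-memory object is :class:`ExpressionMatrix`, a genes x cells
(or genes x samples, for bulk cohorts) numeric matrix with explicit gene and
cell identifiers, a processing-layer tag and a measurement unit.  Keeping
genes on rows mirrors the convention of count matrices emitted by
CellRanger-style pipelines (MTX + features/barcodes).

Readers and writers cover Matrix Market (MTX with ``features.tsv`` /
``barcodes.tsv`` sidecars) and dense CSV/TSV (header row = cell ids, first
column = gene ids).  All paths are gzip-transparent: a ``.gz`` suffix is
honored on both read and write.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

LAYERS = ("raw", "normalized", "scaled")
UNITS = ("umi", "tpm", "fpkm", "bulk_counts")


@dataclass
class ExpressionMatrix:
    """Genes x cells numeric expression matrix with identifiers.

    Parameters
    ----------
    values
        2-D float array, rows = genes, columns = cells/samples.
    gene_ids, cell_ids
        Unique row / column identifiers.
    layer
        Processing stage: ``raw`` (non-negative counts or abundances),
        ``normalized`` (CPM + log1p, or library-normalized input passed
        through), or ``scaled`` (integers in [0, 10]).
    unit
        Measurement unit of the *raw* data: ``umi``, ``tpm``, ``fpkm`` or
        ``bulk_counts``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "raw"
    unit: str = "umi"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (genes x cells)")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        ng, nc = self.values.shape
        if len(self.gene_ids) != ng:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {ng} matrix rows")
        if len(self.cell_ids) != nc:
            raise ValueError(f"{len(self.cell_ids)} cell_ids for {nc} matrix columns")
        if len(set(self.gene_ids)) != ng:
            raise ValueError("gene_ids contain duplicates")
        if len(set(self.cell_ids)) != nc:
            raise ValueError("cell_ids contain duplicates")
        if self.layer == "raw" and self.values.size and self.values.min() < 0:
            raise ValueError("raw layer must be non-negative")
        if self.layer == "scaled" and self.values.size:
            v = self.values
            if v.min() < 0 or v.max() > 10 or not np.array_equal(v, np.trunc(v)):
                raise ValueError("scaled layer must hold integers in [0, 10]")

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:5]}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return replace(self, values=self.values[idx, :], gene_ids=[self.gene_ids[i] for i in idx])

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([pos[c] for c in cells], dtype=int)
        return replace(self, values=self.values[:, idx], cell_ids=[self.cell_ids[i] for i in idx])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.cell_ids), self.layer, self.unit
        )


# ---------------------------------------------------------------------------
# IO helpers
# ---------------------------------------------------------------------------

def _open(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_lines(path: Path) -> list[str]:
    with _open(path, "rt") as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_mtx(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    layer: str = "raw",
    unit: str = "umi",
) -> ExpressionMatrix:
    """Read an MTX triplet (matrix + one-gene-per-line features + barcodes)."""
    mtx_path = Path(mtx_path)
    with _open(mtx_path, "rb") as fh:
        m = spio.mmread(fh)
    values = np.asarray(m.todense() if sparse.issparse(m) else m, dtype=np.float64)
    genes = [ln.split("\t")[0] for ln in _read_lines(Path(features_path))]
    cells = [ln.split("\t")[0] for ln in _read_lines(Path(barcodes_path))]
    return ExpressionMatrix(values, genes, cells, layer=layer, unit=unit)


def write_mtx(
    E: ExpressionMatrix,
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    with _open(Path(mtx_path), "wb") as fh:
        spio.mmwrite(fh, sparse.coo_matrix(E.values))
    with _open(Path(features_path), "wt") as fh:
        fh.write("\n".join(E.gene_ids) + "\n")
    with _open(Path(barcodes_path), "wt") as fh:
        fh.write("\n".join(E.cell_ids) + "\n")


def read_dense(path: str | Path, sep: str | None = None, layer: str = "raw", unit: str = "umi") -> ExpressionMatrix:
    """Read a dense CSV/TSV: header row = cell ids, first column = gene ids."""
    path = Path(path)
    if sep is None:
        name = path.name[:-3] if path.name.endswith(".gz") else path.name
        sep = "\t" if name.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=np.float64), [str(g) for g in df.index], [str(c) for c in df.columns],
        layer=layer, unit=unit,
    )


def write_dense(E: ExpressionMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        name = path.name[:-3] if path.name.endswith(".gz") else path.name
        sep = "\t" if name.endswith((".tsv", ".txt")) else ","
    df = pd.DataFrame(E.values, index=E.gene_ids, columns=E.cell_ids)
    df.to_csv(path, sep=sep)


def read_labels(path: str | Path) -> pd.Series:
    """Read a cell-group label CSV with columns (cell_id, group)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: cell_id, group")
    return pd.Series(df.iloc[:, 1].astype(str).to_numpy(), index=df.iloc[:, 0].astype(str), name="group")
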
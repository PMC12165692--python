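"""Quality filtering, normalization, feature selection and scaling.

The preprocessing chain, in the order the method runs it::

    raw counts
      -> filter_cells_genes   (cell filter first, then gene filter)
      -> normalize_cpm_log    (CPM to 10,000 then ln(1 + x); skipped for
                               length-normalized TPM/FPKM input)
      -> select_hvg           (dispersion-based highly variable genes)
      -> zscore_scale         (per-gene z-score across cells)
      -> minmax_scale_int     (per-gene rescale to integers in [0, 10])

The final integer matrix is what the corpus module turns into gene-token
documents: the integer at (g, c) is the number of copies of gene g's name in
cell c's document.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


class EmptyMatrixError(ValueError):
    """All cells or all genes were removed by a filtering threshold."""


def filter_cells_genes(
    E: ExpressionMatrix,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 20,
) -> ExpressionMatrix:
    """Drop low-complexity cells, then rarely detected genes.

    A cell is kept when it expresses (has a nonzero entry for) at least
    ``min_genes_per_cell`` genes; afterwards a gene is kept when it is
    expressed in at least ``min_cells_per_gene`` of the *surviving* cells.
    Order of survivors is preserved.
    """
    if E.layer != "raw":
        raise ValueError("filter_cells_genes expects a raw-layer matrix")
    nonzero = E.values != 0
    cell_keep = nonzero.sum(axis=0) >= min_genes_per_cell
    if not cell_keep.any():
        raise EmptyMatrixError(
            f"empty matrix after filtering: no cell expresses >= "
            f"{min_genes_per_cell} genes (min_genes_per_cell)"
        )
    gene_keep = nonzero[:, cell_keep].sum(axis=1) >= min_cells_per_gene
    if not gene_keep.any():
        raise EmptyMatrixError(
            f"empty matrix after filtering: no gene is expressed in >= "
            f"{min_cells_per_gene} retained cells (min_cells_per_gene)"
        )
    out = replace(
        E,
        values=E.values[np.ix_(gene_keep, cell_keep)],
        gene_ids=[g for g, k in zip(E.gene_ids, gene_keep) if k],
        cell_ids=[c for c, k in zip(E.cell_ids, cell_keep) if k],
    )
    logger.info(
        "filter_cells_genes: %d/%d cells, %d/%d genes retained",
        out.n_cells, E.n_cells, out.n_genes, E.n_genes,
    )
    return out


def normalize_cpm_log(E: ExpressionMatrix) -> ExpressionMatrix:
    """Depth-normalize to counts-per-10,000 and natural-log transform.

    ``out[g, c] = ln(1 + 10000 * E[g, c] / sum_g E[g, c])``.  TPM and FPKM
    input is already length/depth normalized and passes through unchanged
    (only the layer tag flips to ``normalized``).
    """
    if E.layer != "raw":
        raise ValueError("normalize_cpm_log expects a raw-layer matrix")
    if E.unit in ("tpm", "fpkm"):
        logger.info("normalize_cpm_log: unit=%s, skipping depth normalization", E.unit)
        return replace(E, values=E.values.copy(), layer="normalized")
    totals = E.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total counts cannot be normalized: "
            f"{[E.cell_ids[i] for i in zero[:5]]}"
        )
    out = np.log1p(10000.0 * E.values / totals)
    return replace(E, values=out, layer="normalized")


def select_hvg(E: ExpressionMatrix, n_top: int) -> list[str]:
    """Rank genes by normalized dispersion and return the ``n_top`` best.

    The variability statistic is the mean-binned normalized dispersion of
    log expression (the classic dispersion-based highly-variable-gene
    statistic, computed through scanpy).  Ties are broken by gene id in
    lexicographic order, so the selection is deterministic.
    """
    if E.layer != "normalized":
        raise ValueError("select_hvg expects a normalized-layer matrix")
    if n_top > E.n_genes:
        raise ValueError(f"n_top={n_top} exceeds gene count {E.n_genes}")
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(X=np.ascontiguousarray(E.values.T))
    adata.var_names = E.gene_ids
    sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=min(n_top, E.n_genes))
    disp = np.asarray(adata.var["dispersions_norm"], dtype=float)
    disp = np.where(np.isfinite(disp), disp, -np.inf)
    order = sorted(range(E.n_genes), key=lambda i: (-disp[i], E.gene_ids[i]))
    return [E.gene_ids[i] for i in order[:n_top]]


def zscore_scale(E: ExpressionMatrix, genes: list[str]) -> ExpressionMatrix:
    """Center each selected gene to mean 0, variance 1 across cells.

    Uses the population standard deviation.  Zero-variance genes map to
    all-zero rows (never NaN) so downstream gene sets stay aligned.
    """
    if E.layer != "normalized":
        raise ValueError("zscore_scale expects a normalized-layer matrix")
    if not genes:
        raise ValueError("empty gene list")
    sub = E.subset_genes(genes)
    mu = sub.values.mean(axis=1, keepdims=True)
    sd = sub.values.std(axis=1, keepdims=True)
    out = np.zeros_like(sub.values)
    nz = (sd > 0).ravel()
    out[nz, :] = (sub.values[nz, :] - mu[nz, :]) / sd[nz, :]
    return replace(sub, values=out)


def minmax_scale_int(E: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each gene (feature) to integers in [0, 10].

    ``out[g, c] = int(((x - min_g) / (max_g - min_g)) * 10)`` with int()
    truncating toward zero.  The ratio is evaluated before the factor of 10
    so the per-gene maximum lands exactly on 10.  Constant genes map to 0.
    """
    vals = E.values
    mn = vals.min(axis=1, keepdims=True)
    mx = vals.max(axis=1, keepdims=True)
    span = mx - mn
    out = np.zeros_like(vals)
    nz = (span > 0).ravel()
    out[nz, :] = np.trunc(((vals[nz, :] - mn[nz, :]) / span[nz, :]) * 10.0)
    return replace(E, values=out, layer="scaled")


def preprocess_chain(
    E: ExpressionMatrix,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 20,
    n_top_hvg: int = 2000,
) -> ExpressionMatrix:
    """Full chain: filter -> normalize -> HVG -> z-score -> [0,10] integers."""
    E = filter_cells_genes(E, min_genes_per_cell, min_cells_per_gene)
    E = normalize_cpm_log(E)
    hvg = select_hvg(E, min(n_top_hvg, E.n_genes))
    E = zscore_scale(E, hvg)
    return minmax_scale_int(E)
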
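"""Informative-gene selection: overdispersed genes and iterative markers.

Two complementary feature sets drive dimensionality reduction and
clustering.  *Overdispersed* genes have variance above what their mean
expression predicts (dispersion z-scored within mean bins).  The
*iterative clustering for identifying markers* (ICIM-style) set is built by
recursively bipartitioning cells and accumulating the genes that
significantly distinguish each split — it enriches for cell-type markers
even when no single global axis separates the types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .diffexpr import bh_adjust, mwu_matrix
from .io_core import ExpressionDataset, ValidationError, logger


@dataclass
class FeatureSet:
    """An ordered set of selected gene ids plus selection provenance."""

    method: str  # "overdispersed" | "icim"
    genes: list[str]
    params: dict = field(default_factory=dict)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.genes)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"features": pd.DataFrame({"rank": range(len(self.genes)), "gene": self.genes})}

    def summary(self) -> dict:
        return {"method": self.method, "n_genes": len(self.genes), **self.params}


def _dispersion_zscores(logcpm: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-gene variance/mean dispersion, z-scored within equal-occupancy mean bins."""
    mean = logcpm.mean(axis=1)
    var = logcpm.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    n_genes = mean.size
    n_bins = max(1, min(n_bins, n_genes))
    # equal-occupancy bins over the mean; stable w.r.t. gene order
    order = np.argsort(mean, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)
    z = np.zeros(n_genes)
    for b in range(n_bins):
        sel = bin_of == b
        d = disp[sel]
        sd = d.std()
        z[sel] = (d - d.mean()) / sd if sd > 0 else 0.0
    return z


def overdispersed_genes(
    dataset: ExpressionDataset,
    n_top: int = 500,
    n_bins: int = 20,
) -> FeatureSet:
    """Select the ``n_top`` most overdispersed genes.

    Dispersion is variance/mean of log2(CPM+1); genes are ranked by
    dispersion z-score within 20 equal-occupancy mean bins.  Ties break by
    lexicographic gene id, so the output is deterministic and invariant to
    cell and gene order.
    """
    logcpm = dataset.require_logcpm()
    if dataset.n_cells < 2:
        raise ValidationError("need >= 2 cells to estimate dispersion")
    if n_top == 0:
        return FeatureSet(method="overdispersed", genes=[], params={"n_top": 0})
    if n_top > dataset.n_genes:
        warnings.warn(f"n_top={n_top} exceeds {dataset.n_genes} genes; returning all")
        n_top = dataset.n_genes
    z = _dispersion_zscores(logcpm, n_bins)
    gene_ids = np.array(dataset.gene_ids)
    order = np.lexsort((gene_ids, -z))
    return FeatureSet(
        method="overdispersed",
        genes=list(gene_ids[order][:n_top]),
        params={"n_top": n_top, "n_bins": n_bins},
        provenance=f"{dataset.n_cells} cells",
    )


def icim_select(
    dataset: ExpressionDataset,
    min_cells: int = 10,
    max_depth: int = 8,
    seed: int = 0,
    *,
    min_markers: int = 5,
    alpha: float = 0.01,
    node_n_top: int = 200,
) -> FeatureSet:
    """Iteratively discover cluster-distinguishing marker genes.

    At each node the current cells are bipartitioned by Ward hierarchical
    clustering in their overdispersed-gene space; genes upregulated in
    either branch at BH-adjusted p < ``alpha`` are retained, and the split
    is accepted (and recursed into) only when at least ``min_markers``
    genes pass.  The union over all accepted splits is returned.  The
    procedure is deterministic: Ward linkage and all tie-breaks are
    order-free, and ``seed`` is recorded for provenance.
    """
    if min_cells < 2:
        raise ValidationError("min_cells must be >= 2")
    logcpm = dataset.require_logcpm()
    gene_ids = np.array(dataset.gene_ids)
    if dataset.n_cells < min_cells:
        warnings.warn(f"only {dataset.n_cells} cells (< min_cells={min_cells}); empty set")
        return FeatureSet(method="icim", genes=[], params={"min_cells": min_cells, "seed": seed})

    discovered: set[str] = set()

    def recurse(cell_idx: np.ndarray, depth: int) -> None:
        if depth >= max_depth or cell_idx.size < max(min_cells, 4):
            return
        sub = dataset.subset_cells(np.isin(np.arange(dataset.n_cells), cell_idx))
        od = overdispersed_genes(sub, n_top=min(node_n_top, sub.n_genes))
        if not od.genes:
            return
        gi = dataset.gene_index(od.genes)
        X = logcpm[np.ix_(gi, cell_idx)].T  # cells x features
        if np.allclose(X.var(axis=0), 0):
            return
        Z = sch.linkage(X, method="ward")
        split = sch.fcluster(Z, t=2, criterion="maxclust")
        g1 = cell_idx[split == 1]
        g2 = cell_idx[split == 2]
        if g1.size == 0 or g2.size == 0:
            return
        X1 = logcpm[:, g1].T
        X2 = logcpm[:, g2].T
        markers: set[str] = set()
        for a, b in ((X1, X2), (X2, X1)):
            if a.shape[0] < 2 or b.shape[0] < 2:
                continue
            _, p = mwu_matrix(a, b, alternative="greater")
            p_adj = bh_adjust(p)
            markers.update(gene_ids[p_adj < alpha])
        if len(markers) < min_markers:
            return
        discovered.update(markers)
        for grp in (g1, g2):
            if grp.size >= min_cells:
                recurse(grp, depth + 1)

    recurse(np.arange(dataset.n_cells), 0)
    genes = sorted(discovered)
    logger.info("icim_select: %d genes from %d cells", len(genes), dataset.n_cells)
    return FeatureSet(
        method="icim",
        genes=genes,
        params={"min_cells": min_cells, "max_depth": max_depth, "min_markers": min_markers,
                "alpha": alpha, "seed": seed},
        provenance=f"{dataset.n_cells} cells",
    )
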
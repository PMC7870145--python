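"""Quality filtering and normalization.

Cells are kept when they carry at least ``min_reads`` uniquely assigned
reads (strictly fewer are discarded) and when at least ``marker_min_count``
of the pan-neuronal marker panel genes reach ``marker_min_expr``
log2(CPM+1), which removes contaminating non-neuronal cells.  Expression is
depth-normalized to counts per million (CPM) and all downstream analysis
works in log2(CPM+1) space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ExpressionDataset, ValidationError, logger


@dataclass
class QCParams:
    """Quality-control thresholds.

    ``min_reads`` — minimum uniquely mapped reads per cell (default 100,000;
    cells with *fewer* are removed).  ``marker_min_expr`` — log2(CPM+1)
    level a panel gene must reach to count as expressed (default 8).
    ``marker_min_count`` — how many of the ``marker_panel_size`` panel genes
    must be expressed (default 2 of 6).
    """

    min_reads: int = 100_000
    marker_min_expr: float = 8.0
    marker_min_count: int = 2
    marker_panel_size: int = 6

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValidationError("min_reads must be >= 0")
        if not (0 < self.marker_min_count <= self.marker_panel_size):
            raise ValidationError("need 0 < marker_min_count <= marker_panel_size")


def filter_min_reads(
    dataset: ExpressionDataset,
    params: QCParams,
    *,
    reads_source: str = "counts",
) -> ExpressionDataset:
    """Drop cells with fewer than ``params.min_reads`` total reads.

    ``reads_source`` selects where per-cell totals come from: ``"counts"``
    (column sums of the count matrix — the only option once reads have been
    collapsed to gene counts) or ``"metadata"`` (a ``total_reads`` cell
    annotation carrying upstream uniquely-mapped read counts).
    """
    if dataset.n_cells == 0:
        return dataset
    if reads_source == "metadata":
        totals = dataset.cells["total_reads"].to_numpy(dtype=float)
        if np.isnan(totals).any():
            raise ValidationError("total_reads missing for some cells (metadata source)")
    elif reads_source == "counts":
        totals = dataset.counts.sum(axis=0).astype(float)
    else:
        raise ValidationError(f"unknown reads_source {reads_source!r}")
    keep = totals >= params.min_reads  # 'fewer than' threshold -> strict <
    dataset.cells.loc[~keep, "qc_pass"] = False
    out = dataset.subset_cells(keep)
    out.cells["total_reads"] = totals[keep]
    logger.info("filter_min_reads: kept %d/%d cells", keep.sum(), keep.size)
    return out


def cpm_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Compute the CPM and log2(CPM+1) layers in place (and return dataset).

    Each cell's counts are rescaled to sum to one million; all genes in the
    matrix enter the denominator.  All-zero cells get all-zero CPM and are
    flagged in the cell table rather than raising.
    """
    colsums = dataset.counts.sum(axis=0).astype(np.float64)
    zero = colsums == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cells: CPM set to zero")
        dataset.cells["all_zero"] = zero
    safe = np.where(zero, 1.0, colsums)
    cpm = dataset.counts / safe * 1e6
    dataset.cpm = cpm
    dataset.logcpm = np.log2(cpm + 1.0, dtype=np.float64)
    return dataset


def filter_neuronal(dataset: ExpressionDataset, params: QCParams) -> ExpressionDataset:
    """Keep cells expressing enough pan-neuronal panel genes.

    A cell passes when at least ``marker_min_count`` panel genes (flagged
    ``is_neuronal_marker`` in the gene table) sit at or above
    ``marker_min_expr`` log2(CPM+1).
    """
    logcpm = dataset.require_logcpm()
    panel = dataset.genes["is_neuronal_marker"].to_numpy(dtype=bool)
    n_panel = int(panel.sum())
    if n_panel == 0:
        raise ValidationError("no genes flagged is_neuronal_marker")
    if n_panel != params.marker_panel_size:
        warnings.warn(
            f"neuronal panel has {n_panel} genes, expected {params.marker_panel_size}; "
            "proceeding with the actual panel"
        )
    expressed = (logcpm[panel, :] >= params.marker_min_expr).sum(axis=0)
    keep = expressed >= params.marker_min_count
    dataset.cells.loc[~keep, "qc_pass"] = False
    logger.info("filter_neuronal: kept %d/%d cells", int(keep.sum()), keep.size)
    return dataset.subset_cells(keep)


def qc_summary(counts_by_rule: list[tuple[str, int, int]]) -> pd.DataFrame:
    """One-row-per-rule accounting of cells in/out.

    ``counts_by_rule`` lists (rule name, cells in, cells out) per filter.
    """
    return pd.DataFrame(
        [{"rule": rule, "cells_in": n_in, "cells_out": n_out,
          "cells_removed": n_in - n_out}
         for rule, n_in, n_out in counts_by_rule],
        columns=["rule", "cells_in", "cells_out", "cells_removed"],
    )
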
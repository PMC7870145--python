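"""One-vs-rest differential expression and cluster signature sets.

For each cluster, every gene is tested with a Mann-Whitney U test against
the pooled remaining clusters; p-values are Benjamini-Hochberg adjusted
within the cluster's test family, and genes at adjusted p < alpha
(default 0.01, strict) upregulated in the cluster form its *signature set*
— the unit compared across stages when matching cluster identities.
Stage-pair contrasts rank all genes by two-sided U-test p-value and keep
the top-k (default 150) per pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionDataset, ValidationError, logger

#: Largest combined sample size for which the exact U distribution is used.
EXACT_MAX_N = 20


def mwu_test(x, y, alternative: str = "two_sided") -> tuple[float, float]:
    """Mann-Whitney U test of sample ``x`` against sample ``y``.

    U uses midrank tie handling.  The p-value is exact for small samples
    (combined n <= 20 with no ties) and otherwise a normal approximation
    with tie and continuity corrections.  ``alternative`` is ``two_sided``
    or ``greater`` (x stochastically greater than y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mwu_test requires non-empty samples")
    if alternative not in ("two_sided", "greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    alt = "two-sided" if alternative == "two_sided" else "greater"
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative=alt, method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def mwu_matrix(X: np.ndarray, Y: np.ndarray, alternative: str = "greater") -> tuple[np.ndarray, np.ndarray]:
    """Columnwise U tests of ``X`` (n1 x G) against ``Y`` (n2 x G).

    Uses the tie-corrected normal approximation throughout (group sizes in
    one-vs-rest contrasts are far beyond the exact-branch regime).
    Returns (U, p) arrays of length G.
    """
    if X.shape[1] != Y.shape[1]:
        raise ValidationError("gene dimension mismatch")
    alt = "two-sided" if alternative == "two_sided" else "greater"
    res = scipy.stats.mannwhitneyu(X, Y, alternative=alt, method="asymptotic",
                                   use_continuity=True, axis=0)
    return np.asarray(res.statistic, dtype=float), np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)


def one_vs_rest_mwu(
    X: np.ndarray, labels: np.ndarray, alternative: str = "greater"
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """U tests of every cluster against the rest, sharing one ranking pass.

    In one-vs-rest contrasts the pooled sample is the same for every
    cluster, so genes are midranked once over all non-noise cells and each
    cluster's U statistic follows from its rank sum; the tie term
    sum(t^3 - t) is recovered per gene from the midrank variance identity
    sum(r - rbar)^2 = (n^3 - n)/12 - sum(t^3 - t)/12.  p-values use the
    tie- and continuity-corrected normal approximation, matching
    :func:`mwu_matrix` on the same contrast.
    """
    labels = np.asarray(labels)
    keep = labels >= 0
    Xk = np.asarray(X, dtype=float)[keep]
    lk = labels[keep]
    n = Xk.shape[0]
    R = scipy.stats.rankdata(Xk, axis=0)
    dev2 = ((R - (n + 1) / 2.0) ** 2).sum(axis=0)
    tie_term = (n**3 - n) - 12.0 * dev2
    tie_term = np.maximum(tie_term, 0.0)
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for c in sorted(int(v) for v in np.unique(lk)):
        mask = lk == c
        n1 = int(mask.sum())
        n2 = n - n1
        U = R[mask].sum(axis=0) - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
        sigma = np.sqrt(np.maximum(sigma2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            if alternative == "greater":
                z = (U - mu - 0.5) / sigma
                p = scipy.stats.norm.sf(z)
            else:
                z = (np.abs(U - mu) - 0.5) / sigma
                p = 2.0 * scipy.stats.norm.sf(z)
        p = np.where(sigma == 0, 1.0, np.minimum(p, 1.0))
        out[c] = (U, p)
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per (cluster, gene) one-vs-rest test results."""

    table: pd.DataFrame  # cluster, gene, U, p, p_adj, direction, mean_in, mean_out
    alpha: float

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"de_table": self.table}


@dataclass
class SignatureSet:
    """Per-cluster ordered sets of one-vs-rest upregulated genes."""

    signatures: dict[int, list[str]]
    alpha: float
    stage: str | None = None
    lineage_scope: tuple[str, ...] | None = None
    de: DEResult | None = None
    low_power_clusters: list[int] = field(default_factory=list)

    def clusters(self) -> list[int]:
        return sorted(self.signatures)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        rows = [
            {"cluster": c, "rank": i, "gene": g}
            for c in sorted(self.signatures)
            for i, g in enumerate(self.signatures[c])
        ]
        return {"signatures": pd.DataFrame(rows, columns=["cluster", "rank", "gene"])}

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "stage": self.stage,
            "n_clusters": len(self.signatures),
            "signature_sizes": {str(c): len(g) for c, g in sorted(self.signatures.items())},
        }


def cluster_signatures(
    dataset: ExpressionDataset,
    labels: np.ndarray,
    alpha: float = 0.01,
    *,
    alternative: str = "greater",
    stage: str | None = None,
) -> SignatureSet:
    """One-vs-rest DE per cluster; keep upregulated genes at adjusted p < alpha.

    ``labels`` assigns each cell an integer cluster; -1 marks noise cells,
    which are excluded entirely.  BH correction is applied within each
    cluster's family of per-gene tests.  Clusters with fewer than 3 cells
    are still tested but flagged low-power.
    """
    labels = np.asarray(labels)
    if labels.shape != (dataset.n_cells,):
        raise ValidationError("labels length must equal number of cells")
    logcpm = dataset.require_logcpm()
    keep = labels >= 0
    cluster_ids = sorted(int(c) for c in np.unique(labels[keep]))
    if len(cluster_ids) < 2:
        raise ValidationError("need >= 2 non-noise clusters for one-vs-rest DE")

    X = logcpm.T  # cells x genes
    gene_ids = np.array(dataset.gene_ids)
    rows = []
    signatures: dict[int, list[str]] = {}
    low_power = []
    tests = one_vs_rest_mwu(X, labels, alternative=alternative)
    for c in cluster_ids:
        in_mask = labels == c
        out_mask = keep & ~in_mask
        if in_mask.sum() < 3:
            low_power.append(c)
        U, p = tests[c]
        p_adj = bh_adjust(p)
        mean_in = X[in_mask].mean(axis=0)
        mean_out = X[out_mask].mean(axis=0)
        up = mean_in > mean_out
        sig_mask = (p_adj < alpha) & up  # strictly below alpha
        order = np.lexsort((gene_ids[sig_mask], p_adj[sig_mask]))
        signatures[c] = list(gene_ids[sig_mask][order])
        df = pd.DataFrame({
            "cluster": c, "gene": gene_ids, "U": U, "p": p, "p_adj": p_adj,
            "direction": np.where(up, "up", "down"),
            "mean_in": mean_in, "mean_out": mean_out,
        })
        rows.append(df)
    if low_power:
        warnings.warn(f"clusters {low_power} have < 3 cells; signatures are low-power")
    table = pd.concat(rows, ignore_index=True)
    logger.info("cluster_signatures: %d clusters, sizes %s",
                len(cluster_ids), {c: len(s) for c, s in signatures.items()})
    return SignatureSet(signatures=signatures, alpha=alpha, stage=stage,
                        de=DEResult(table=table, alpha=alpha),
                        low_power_clusters=low_power)


def stage_pair_top_genes(
    dataset: ExpressionDataset,
    stage_a: str,
    stage_b: str,
    k: int = 150,
) -> list[str]:
    """Top-k most differentially expressed genes between two stages.

    Genes are ranked by two-sided U-test p-value ascending, ties broken by
    absolute mean log2(CPM+1) difference descending, then gene id.
    """
    if stage_a == stage_b:
        raise ValidationError("stage_a and stage_b must differ")
    if k < 1:
        raise ValidationError("k must be >= 1")
    stages = dataset.cells["stage"].to_numpy()
    mask_a = stages == stage_a
    mask_b = stages == stage_b
    if not mask_a.any() or not mask_b.any():
        raise ValidationError(f"stage {stage_a if not mask_a.any() else stage_b} has no cells")
    X = dataset.require_logcpm().T
    _, p = mwu_matrix(X[mask_a], X[mask_b], alternative="two_sided")
    mean_diff = np.abs(X[mask_a].mean(axis=0) - X[mask_b].mean(axis=0))
    gene_ids = np.array(dataset.gene_ids)
    order = np.lexsort((gene_ids, -mean_diff, p))
    if k > len(gene_ids):
        warnings.warn(f"k={k} exceeds {len(gene_ids)} genes; returning all")
        k = len(gene_ids)
    return list(gene_ids[order][:k])
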
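"""Transcriptomic diversity, birth-order covariation, and dendrograms.

Diversity is quantified at two levels within each (stage, lineage): at the
cell level as each cell's mean inverse Euclidean distance to all other
cells in a low-dimensional embedding (higher = more homogeneous; the
pipeline defaults to the denoised PC feature space, with 2-D layouts
available), and at the cluster level as the mean Pearson correlation
between cluster centroids restricted to differentially expressed genes,
with a bootstrap 95% CI over cluster pairs.

Birth-order covariation asks whether types born closer together in a
neuroblast lineage have more similar transcriptomes.  For each type X the
larger of its earlier-born/later-born groups (size >= 5) is ranked by
correlation with X and by birth distance from X; the average Spearman rho
over eligible types is the observed statistic, and its null distribution
comes from uniformly re-shuffling the birth order.  Positive rho means
nearer-born implies more similar.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
import sklearn.decomposition

from .cluster import Embedding
from .io_core import ExpressionDataset, ValidationError, logger


# ---------------------------------------------------------------------------
# Cell- and cluster-level similarity
# ---------------------------------------------------------------------------

@dataclass
class CellSimilarity:
    values: np.ndarray  # per-cell mean inverse distance
    mean: float
    sd: float
    n_zero_pairs: int = 0


def cell_level_similarity(embedding, cells=None) -> CellSimilarity:
    """Per-cell mean inverse Euclidean distance to all other cells.

    ``embedding`` is an :class:`~pnatlas.cluster.Embedding` or a bare
    coordinate matrix (cells x dims, any dimensionality).  ``cells``
    optionally restricts the computation to a subset of the embedding's
    cell ids (e.g. one stage within a multi-stage layout).  Coincident
    cell pairs (distance zero) are excluded from the mean, with a warning
    that counts them.
    """
    if isinstance(embedding, Embedding):
        coords = np.asarray(embedding.coords, dtype=float)
        if cells is not None:
            wanted = set(cells)
            sel = np.array([c in wanted for c in embedding.cell_ids])
            coords = coords[sel]
    else:
        coords = np.asarray(embedding, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 cells for cell-level similarity")
    D = ssd.squareform(ssd.pdist(coords))
    off = ~np.eye(n, dtype=bool)
    zero = (D == 0) & off
    n_zero = int(zero.sum() // 2)
    if n_zero:
        warnings.warn(f"{n_zero} coincident cell pairs excluded from similarity")
    with np.errstate(divide="ignore"):
        inv = np.where((D > 0) & off, 1.0 / np.where(D > 0, D, 1.0), 0.0)
    counts = (off & (D > 0)).sum(axis=1)
    values = inv.sum(axis=1) / np.maximum(counts, 1)
    return CellSimilarity(values=values, mean=float(values.mean()),
                          sd=float(values.std(ddof=0)), n_zero_pairs=n_zero)


def bootstrap_ci(values, n_iter: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Percentile 95% CI of the mean by bootstrap resampling."""
    v = np.asarray(values, dtype=float)
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if v.size == 1:
        warnings.warn("single value: degenerate CI")
        return float(v[0]), float(v[0])
    if v.size < 2:
        raise ValidationError("need >= 1 value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_iter, v.size))
    means = v[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class ClusterSimilarity:
    matrix: pd.DataFrame  # cluster x cluster Pearson correlations
    pair_values: np.ndarray
    mean: float
    ci: tuple[float, float]


def cluster_level_similarity(
    dataset: ExpressionDataset,
    labels: np.ndarray,
    de_genes: list[str],
    *,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ClusterSimilarity:
    """Mean pairwise Pearson correlation of cluster centroids on DE genes."""
    if not de_genes:
        raise ValidationError("de_genes must be non-empty")
    labels = np.asarray(labels)
    cluster_ids = sorted(int(c) for c in np.unique(labels[labels >= 0]))
    if len(cluster_ids) < 2:
        raise ValidationError("need >= 2 clusters")
    idx = dataset.gene_index(de_genes)
    logcpm = dataset.require_logcpm()
    centroids = np.stack([logcpm[np.ix_(idx, np.flatnonzero(labels == c))].mean(axis=1)
                          for c in cluster_ids])
    sds = centroids.std(axis=1)
    constant = sds == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant centroids excluded from correlations")
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(centroids)
    mat = pd.DataFrame(C, index=cluster_ids, columns=cluster_ids)
    pair_vals = np.array([
        C[i, j] for i, j in itertools.combinations(range(len(cluster_ids)), 2)
        if not (constant[i] or constant[j])
    ])
    mean = float(pair_vals.mean())
    ci = bootstrap_ci(pair_vals, n_iter=n_bootstrap, seed=seed)
    return ClusterSimilarity(matrix=mat, pair_values=pair_vals, mean=mean, ci=ci)


@dataclass
class DiversityReport:
    """Per (stage, lineage) cell- and cluster-level similarity statistics."""

    table: pd.DataFrame  # stage, lineage, n_cells, cell_mean, cell_sd,
                         # n_clusters, cluster_mean, ci_low, ci_high

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"diversity": self.table}


# ---------------------------------------------------------------------------
# Birth-order covariation
# ---------------------------------------------------------------------------

def type_correlation_matrix(
    dataset: ExpressionDataset,
    *,
    type_col: str = "type_label",
    n_pcs: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pearson correlation between type centroids in PC space, birth-ordered.

    PCA runs over all genes detected (nonzero in the cell subset); each
    type's centroid is the mean of its cells' PC coordinates.  Rows and
    columns are sorted by birth rank.  Returns (matrix, birth_ranks).
    """
    cells = dataset.cells
    known = cells[type_col].notna() & cells["birth_rank"].notna()
    sub = dataset.subset_cells(known.to_numpy())
    types = sub.cells.groupby(type_col, observed=True)["birth_rank"].first().sort_values()
    if len(types) < 3:
        raise ValidationError("need >= 3 types with known birth ranks")
    detected = (sub.counts.sum(axis=1) > 0)
    X = sub.require_logcpm()[detected, :].T  # cells x detected genes
    k = n_pcs if n_pcs is not None else min(20, len(types) - 1)
    if k > len(types) - 1:
        warnings.warn(f"n_pcs={k} capped at n_types-1={len(types) - 1}")
        k = len(types) - 1
    k = min(k, X.shape[0] - 1, X.shape[1])
    pcs = sklearn.decomposition.PCA(n_components=k, svd_solver="randomized",
                                    random_state=0).fit_transform(X)
    centroids = np.stack([pcs[(sub.cells[type_col] == t).to_numpy()].mean(axis=0)
                          for t in types.index])
    C = np.corrcoef(centroids)
    mat = pd.DataFrame(C, index=types.index, columns=types.index)
    return mat, types.to_numpy(dtype=float)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho via midranks; 0 when either vector is constant."""
    ra = scipy.stats.rankdata(a)
    rb = scipy.stats.rankdata(b)
    if ra.std() == 0 or rb.std() == 0:
        return 0.0
    return float(np.corrcoef(ra, rb)[0, 1])


def birth_order_stat(corr: np.ndarray | pd.DataFrame, birth_ranks,
                     min_group: int = 5) -> float:
    """Average Spearman concordance between similarity and birth proximity.

    For each type X, the earlier-born or later-born group with more types
    is selected (tie: earlier); X is skipped when that group has fewer than
    ``min_group`` types.  Within the group, rho is the Spearman correlation
    of correlation-with-X against *negative* birth distance, so nearer-born
    and more-similar rank together and positive rho means the transcriptome
    tracks birth order.
    """
    C = np.asarray(corr, dtype=float)
    ranks = np.asarray(birth_ranks, dtype=float)
    n = ranks.size
    if C.shape != (n, n):
        raise ValidationError("correlation matrix and birth ranks disagree in size")
    rhos = []
    for i in range(n):
        earlier = np.flatnonzero(ranks < ranks[i])
        later = np.flatnonzero(ranks > ranks[i])
        group = earlier if earlier.size >= later.size else later
        if group.size < min_group:
            continue
        sims = C[i, group]
        dist = np.abs(ranks[group] - ranks[i])
        rhos.append(_spearman(sims, -dist))
    if not rhos:
        raise ValidationError(f"no type has an eligible group of >= {min_group}")
    return float(np.mean(rhos))


@dataclass
class BirthOrderResult:
    observed: float
    permuted: np.ndarray
    p_value: float
    n_iter: int
    min_group: int
    corrected: bool = False

    def summary(self) -> dict:
        return {"observed": self.observed, "p_value": self.p_value,
                "n_iter": self.n_iter, "min_group": self.min_group,
                "corrected": self.corrected,
                "null_mean": float(self.permuted.mean()),
                "null_sd": float(self.permuted.std(ddof=0))}


def birth_order_permutation(
    corr: np.ndarray | pd.DataFrame,
    birth_ranks,
    n_iter: int = 5000,
    seed: int = 0,
    *,
    min_group: int = 5,
    plus_one_correction: bool = False,
) -> BirthOrderResult:
    """Permutation test of the birth-order statistic.

    Birth ranks are shuffled uniformly ``n_iter`` times; the p-value is the
    fraction of permuted statistics strictly greater than the observed one
    (so it can be exactly 0).  ``plus_one_correction`` switches to the
    (k+1)/(N+1) estimator.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    ranks = np.asarray(birth_ranks, dtype=float)
    observed = birth_order_stat(corr, ranks, min_group=min_group)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_iter)
    for it in range(n_iter):
        permuted[it] = birth_order_stat(corr, rng.permutation(ranks), min_group=min_group)
    k = int((permuted > observed).sum())
    p = (k + 1) / (n_iter + 1) if plus_one_correction else k / n_iter
    logger.info("birth_order_permutation: obs=%.3f p=%.4g (n_iter=%d)", observed, p, n_iter)
    return BirthOrderResult(observed=observed, permuted=permuted, p_value=float(p),
                            n_iter=n_iter, min_group=min_group,
                            corrected=plus_one_correction)


def enumerate_birth_order_null(corr, birth_ranks, min_group: int = 5) -> np.ndarray:
    """Exact null: the statistic under every permutation of the birth ranks.

    Feasible for small numbers of types; used to validate the sampled test.
    """
    ranks = np.asarray(birth_ranks, dtype=float)
    return np.array([
        birth_order_stat(corr, np.array(p), min_group=min_group)
        for p in itertools.permutations(ranks)
    ])


# ---------------------------------------------------------------------------
# Dendrograms
# ---------------------------------------------------------------------------

def dendrogram_order(profiles: pd.DataFrame) -> tuple[np.ndarray, list, str]:
    """Complete-linkage (farthest-point) tree with optimal leaf ordering.

    ``profiles`` holds one centroid per row.  Returns the linkage matrix,
    the leaf labels in optimized order (successive-leaf distances minimal),
    and a Newick string.  Deterministic and invariant to row order up to
    the optimal-ordering objective.
    """
    if len(profiles) < 2:
        raise ValidationError("need >= 2 profiles")
    labels = [str(i) for i in profiles.index]
    order_in = np.argsort(labels, kind="stable")  # canonicalize input order
    X = profiles.to_numpy(dtype=float)[order_in]
    labels = [labels[i] for i in order_in]
    D = ssd.pdist(X)
    Z = sch.linkage(D, method="complete")
    Z = sch.optimal_leaf_ordering(Z, D)
    leaves = [labels[i] for i in sch.leaves_list(Z)]
    newick = _to_newick(sch.to_tree(Z), labels)
    return Z, leaves, newick


def _to_newick(node, labels) -> str:
    def rec(n, parent_dist) -> str:
        length = max(parent_dist - n.dist, 0.0)
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.6g}"
        return f"({rec(n.left, n.dist)},{rec(n.right, n.dist)}):{length:.6g}"

    return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)});"
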
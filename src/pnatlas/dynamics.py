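"""Globally dynamic genes across stages and their temporal profile groups.

The top-k most differentially expressed genes from every unordered stage
pair are pooled into a dynamic-gene union.  Each gene's per-stage median
log2(CPM+1) profile is normalized so its maximum equals one, the profiles
are embedded in 2-D and density-clustered, and each group's mean profile
is classified as monotone up, monotone down, or trendless.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import stage_pair_top_genes
from .io_core import ExpressionDataset, ValidationError, logger, stage_sort_key

#: Minimum normalized first-to-last change for an up/down call.
TREND_DELTA = 0.2
#: A single monotonicity violation up to this size is tolerated.
TREND_TOL = 0.05


@dataclass
class DynamicGeneGroups:
    """Normalized per-stage median profiles with group ids and trends."""

    table: pd.DataFrame  # gene, median_<stage>..., norm_<stage>..., group, trend
    stages: list[str]

    def trend_of(self) -> pd.Series:
        return self.table.set_index("gene")["trend"]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"dynamic_groups": self.table}

    def summary(self) -> dict:
        counts = self.table["trend"].value_counts().to_dict()
        return {"n_genes": len(self.table),
                "n_groups": int(self.table["group"].nunique()),
                "trend_counts": {k: int(v) for k, v in sorted(counts.items())}}


def dynamic_gene_union(dataset: ExpressionDataset, k: int = 150) -> list[str]:
    """Union of top-k stage-pair DE genes over all unordered stage pairs."""
    stages = stage_sort_key(dataset.cells["stage"].dropna().unique(), dataset.stage_order)
    if len(stages) < 2:
        raise ValidationError("need >= 2 stages for dynamic-gene identification")
    union: set[str] = set()
    for a, b in itertools.combinations(stages, 2):
        union.update(stage_pair_top_genes(dataset, a, b, k=k))
    logger.info("dynamic_gene_union: %d genes from %d stage pairs",
                len(union), len(stages) * (len(stages) - 1) // 2)
    return sorted(union)


def classify_trend(profile: np.ndarray, delta: float = TREND_DELTA,
                   tol: float = TREND_TOL) -> str:
    """Classify a normalized profile as ``up``, ``down`` or ``none``.

    ``up`` requires last >= first + delta and monotone non-decreasing steps,
    allowing at most one counter-step no deeper than ``tol``; ``down`` is
    symmetric.
    """
    p = np.asarray(profile, dtype=float)
    diffs = np.diff(p)

    def monotone(d: np.ndarray) -> bool:
        viol = d[d < 0]
        return viol.size <= 1 and (viol.size == 0 or -viol.min() <= tol + 1e-12)

    if p[-1] >= p[0] + delta and monotone(diffs):
        return "up"
    if p[0] >= p[-1] + delta and monotone(-diffs):
        return "down"
    return "none"


def stage_median_profiles(dataset: ExpressionDataset, genes: list[str]) -> pd.DataFrame:
    """Per-gene per-stage median log2(CPM+1) over qc-passing cells."""
    logcpm = dataset.require_logcpm()
    stages = stage_sort_key(dataset.cells["stage"].dropna().unique(), dataset.stage_order)
    idx = dataset.gene_index(genes)
    cols = {}
    for s in stages:
        mask = (dataset.cells["stage"] == s).to_numpy()
        cols[s] = np.median(logcpm[np.ix_(idx, np.flatnonzero(mask))], axis=1)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


def profile_and_group(dataset: ExpressionDataset, genes: list[str],
                      seed: int = 0, *, min_group_size: int = 10) -> DynamicGeneGroups:
    """Group dynamic genes by the shape of their normalized stage profiles.

    Profiles (median per stage, scaled so max = 1) are tSNE-embedded and
    density-clustered; each group's trend is read off its mean profile.
    Genes the density clusterer leaves unassigned are classified on their
    own profile as singleton groups.  All-zero genes are excluded.
    """
    if not genes:
        raise ValidationError("empty gene set")
    med = stage_median_profiles(dataset, genes)
    stages = list(med.columns)
    maxima = med.max(axis=1)
    zero = maxima <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes with all-zero medians excluded")
        med = med.loc[~zero]
        maxima = maxima[~zero]
    norm = med.div(maxima, axis=0)

    from .cluster import Embedding, density_cluster  # deferred: avoids an import cycle
    import sklearn.manifold

    X = norm.to_numpy()
    if len(norm) >= max(8, min_group_size):
        perplexity = min(30.0, max(2.0, (len(norm) - 1) / 4.0))
        coords = sklearn.manifold.TSNE(n_components=2, random_state=seed, init="pca",
                                       perplexity=perplexity).fit_transform(X)
        emb = Embedding(coords=np.asarray(coords, dtype=float),
                        cell_ids=list(norm.index), method="tsne",
                        features=stages, seed=seed)
        assign = density_cluster(emb, min_cluster_size=min_group_size)
        labels = assign.labels.copy()
    else:
        labels = np.full(len(norm), -1, dtype=int)
    # unassigned profiles become singleton groups with their own trend
    next_id = labels.max() + 1 if (labels >= 0).any() else 0
    for i in np.flatnonzero(labels < 0):
        labels[i] = next_id
        next_id += 1

    trend_by_group = {}
    for g in np.unique(labels):
        mean_profile = X[labels == g].mean(axis=0)
        trend_by_group[int(g)] = classify_trend(mean_profile)

    table = pd.DataFrame({"gene": norm.index})
    for s in stages:
        table[f"median_{s}"] = med[s].to_numpy()
    for s in stages:
        table[f"norm_{s}"] = norm[s].to_numpy()
    table["group"] = labels
    table["trend"] = [trend_by_group[int(g)] for g in labels]
    logger.info("profile_and_group: %d genes, %d groups", len(table),
                int(table["group"].nunique()))
    return DynamicGeneGroups(table=table, stages=stages)
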
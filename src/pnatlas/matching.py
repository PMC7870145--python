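"""Cross-stage cluster matching.

Clusters representing the same neuron type at two developmental stages are
matched two ways.  *Signature matching* computes the Jaccard similarity of
the clusters' one-vs-rest upregulated gene sets for every cluster pair
across the two stages and calls a pair matched when the clusters are
mutually each other's most similar cluster (reciprocal best hit); one-way
best hits are reported with their direction.  *Marker matching* searches
each cluster's signature for single genes or two-gene combinations
uniquely expressed in that cluster at each stage, and links clusters whose
unique marker and lineage agree.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .diffexpr import SignatureSet
from .io_core import ExpressionDataset, ValidationError, logger


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b|; defined as 0 (with a warning) when both are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        warnings.warn("jaccard of two empty sets: defined as 0")
        return 0.0
    return len(a & b) / len(a | b)


@dataclass
class MatchResult:
    """Cross-stage cluster pairs with Jaccard scores and match classes."""

    stage_a: str | None
    stage_b: str | None
    pairs: pd.DataFrame   # cluster_a, cluster_b, jaccard, match_class
    matrix: pd.DataFrame  # full Jaccard matrix, rows = stage-a clusters

    def two_way(self) -> list[tuple[int, int]]:
        sel = self.pairs[self.pairs["match_class"] == "two_way"]
        return [(int(r.cluster_a), int(r.cluster_b)) for r in sel.itertuples()]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        mat = self.matrix.reset_index().rename(columns={"index": "cluster_a"})
        return {"matches": self.pairs, "jaccard_matrix": mat}

    def summary(self) -> dict:
        return {
            "stage_a": self.stage_a, "stage_b": self.stage_b,
            "n_two_way": int((self.pairs["match_class"] == "two_way").sum()),
            "n_one_way": int(self.pairs["match_class"].astype(str)
                             .str.startswith("one_way").sum()),
        }


def _argmax_unique(row: np.ndarray) -> int | None:
    """Index of the strict maximum, or None on a tie (stringency rule)."""
    best = row.max()
    idx = np.flatnonzero(row == best)
    return int(idx[0]) if idx.size == 1 else None


def signature_match(sig_a: SignatureSet, sig_b: SignatureSet) -> MatchResult:
    """Reciprocal-best-hit matching of cluster signatures across two stages.

    Clusters with empty signatures are excluded (and reported via a
    warning); argmax ties yield no match in the tied direction.
    """
    a_ids = [c for c in sig_a.clusters() if sig_a.signatures[c]]
    b_ids = [c for c in sig_b.clusters() if sig_b.signatures[c]]
    dropped = (set(sig_a.clusters()) - set(a_ids)) | (set(sig_b.clusters()) - set(b_ids))
    if dropped:
        warnings.warn(f"clusters with empty signatures excluded from matching: {sorted(dropped)}")
    if not a_ids or not b_ids:
        raise ValidationError("each stage needs >= 1 cluster with a non-empty signature")

    J = np.zeros((len(a_ids), len(b_ids)))
    for i, ca in enumerate(a_ids):
        for j, cb in enumerate(b_ids):
            J[i, j] = jaccard(sig_a.signatures[ca], sig_b.signatures[cb])

    best_ab = [_argmax_unique(J[i, :]) for i in range(len(a_ids))]
    best_ba = [_argmax_unique(J[:, j]) for j in range(len(b_ids))]
    rows = []
    for i, j in enumerate(best_ab):
        if j is None:
            continue
        if best_ba[j] == i:
            rows.append({"cluster_a": a_ids[i], "cluster_b": b_ids[j],
                         "jaccard": J[i, j], "match_class": "two_way"})
        else:
            rows.append({"cluster_a": a_ids[i], "cluster_b": b_ids[j],
                         "jaccard": J[i, j], "match_class": "one_way_ab"})
    for j, i in enumerate(best_ba):
        if i is None or best_ab[i] == j:
            continue  # tie, or already reported as two_way
        rows.append({"cluster_a": a_ids[i], "cluster_b": b_ids[j],
                     "jaccard": J[i, j], "match_class": "one_way_ba"})
    pairs = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "jaccard", "match_class"])
    pairs = pairs.sort_values(["cluster_a", "cluster_b"]).reset_index(drop=True)
    matrix = pd.DataFrame(J, index=pd.Index(a_ids, name="cluster_a"),
                          columns=[str(c) for c in b_ids])
    logger.info("signature_match %s-%s: %d two-way of %dx%d clusters",
                sig_a.stage, sig_b.stage,
                int((pairs["match_class"] == "two_way").sum()), len(a_ids), len(b_ids))
    return MatchResult(stage_a=sig_a.stage, stage_b=sig_b.stage, pairs=pairs, matrix=matrix)


# ---------------------------------------------------------------------------
# Marker-based matching
# ---------------------------------------------------------------------------

@dataclass
class MarkerMatch:
    """Markers (genes or gene pairs) uniquely selecting one cluster per stage."""

    stage_a: str | None
    stage_b: str | None
    table: pd.DataFrame  # marker, cluster_a, cluster_b, lineage_a, lineage_b, lineage_consistent
    unmatched_a: list[int] = field(default_factory=list)
    unmatched_b: list[int] = field(default_factory=list)

    def matched_pairs(self) -> list[tuple[int, int]]:
        sel = self.table[self.table["lineage_consistent"]]
        return sorted({(int(r.cluster_a), int(r.cluster_b)) for r in sel.itertuples()})

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"marker_matches": self.table}


def _expressed_fraction(dataset: ExpressionDataset, gene_rows: np.ndarray,
                        labels: np.ndarray, cluster_ids: list[int],
                        expr_threshold: float) -> np.ndarray:
    """Fraction of each cluster's cells with logcpm >= threshold; (genes x clusters)."""
    logcpm = dataset.require_logcpm()
    hot = logcpm[gene_rows, :] >= expr_threshold
    out = np.empty((gene_rows.size, len(cluster_ids)))
    for j, c in enumerate(cluster_ids):
        sel = labels == c
        out[:, j] = hot[:, sel].mean(axis=1)
    return out


def _cluster_lineages(dataset: ExpressionDataset, labels: np.ndarray,
                      cluster_ids: list[int]) -> dict[int, str | None]:
    lin = dataset.cells["lineage"]
    out = {}
    for c in cluster_ids:
        vals = lin[labels == c].dropna()
        out[c] = vals.mode().iloc[0] if len(vals) else None
    return out


def _unique_markers_per_cluster(
    dataset: ExpressionDataset,
    labels: np.ndarray,
    signatures: SignatureSet,
    expr_threshold: float,
    frac_threshold: float,
    max_pair_search: int,
) -> dict[tuple, int]:
    """Map marker (1- or 2-gene tuple) -> the unique cluster it selects."""
    cluster_ids = [c for c in signatures.clusters() if signatures.signatures[c]]
    candidates = sorted({g for c in cluster_ids
                         for g in signatures.signatures[c][:max_pair_search]})
    if not candidates:
        return {}
    gene_rows = dataset.gene_index(candidates)
    frac = _expressed_fraction(dataset, gene_rows, labels, cluster_ids, expr_threshold)
    expressed = frac >= frac_threshold  # genes x clusters
    markers: dict[tuple, int] = {}
    for gi, g in enumerate(candidates):
        cols = np.flatnonzero(expressed[gi])
        if cols.size == 1:
            markers[(g,)] = cluster_ids[int(cols[0])]
    # two-gene conjunctions among each cluster's own signature genes
    cand_idx = {g: i for i, g in enumerate(candidates)}
    for j, c in enumerate(cluster_ids):
        sig = [g for g in signatures.signatures[c][:max_pair_search]]
        for g1, g2 in itertools.combinations(sorted(sig), 2):
            both = expressed[cand_idx[g1]] & expressed[cand_idx[g2]]
            cols = np.flatnonzero(both)
            if cols.size == 1 and cluster_ids[int(cols[0])] == c:
                markers[(g1, g2)] = c
    return markers


def marker_match(
    dataset_a: ExpressionDataset,
    labels_a: ClusterAssignment,
    sig_a: SignatureSet,
    dataset_b: ExpressionDataset,
    labels_b: ClusterAssignment,
    sig_b: SignatureSet,
    *,
    expr_threshold: float = 4.0,
    frac_threshold: float = 0.5,
    max_pair_search: int = 200,
) -> MarkerMatch:
    """Match clusters across two stages via uniquely expressed markers.

    A gene (or conjunction of two genes) is *expressed in* a cluster when
    at least ``frac_threshold`` of its cells sit at or above
    ``expr_threshold`` log2(CPM+1).  Markers unique to one cluster at both
    stages link those clusters; the link is accepted when the clusters'
    majority lineages agree.  Clusters with no unique marker are reported
    unmatched.
    """
    la = np.asarray(labels_a.labels)
    lb = np.asarray(labels_b.labels)
    m_a = _unique_markers_per_cluster(dataset_a, la, sig_a, expr_threshold,
                                      frac_threshold, max_pair_search)
    m_b = _unique_markers_per_cluster(dataset_b, lb, sig_b, expr_threshold,
                                      frac_threshold, max_pair_search)
    lin_a = _cluster_lineages(dataset_a, la, sig_a.clusters())
    lin_b = _cluster_lineages(dataset_b, lb, sig_b.clusters())
    rows = []
    for marker, ca in m_a.items():
        if marker in m_b:
            cb = m_b[marker]
            consistent = (lin_a.get(ca) is not None and lin_a.get(ca) == lin_b.get(cb))
            rows.append({"marker": "+".join(marker), "cluster_a": ca, "cluster_b": cb,
                         "lineage_a": lin_a.get(ca), "lineage_b": lin_b.get(cb),
                         "lineage_consistent": consistent})
    table = pd.DataFrame(rows, columns=["marker", "cluster_a", "cluster_b",
                                        "lineage_a", "lineage_b", "lineage_consistent"])
    table = table.sort_values(["cluster_a", "cluster_b", "marker"]).reset_index(drop=True)
    matched_a = set(table.loc[table["lineage_consistent"], "cluster_a"])
    matched_b = set(table.loc[table["lineage_consistent"], "cluster_b"])
    result = MarkerMatch(
        stage_a=sig_a.stage, stage_b=sig_b.stage, table=table,
        unmatched_a=sorted(set(sig_a.clusters()) - matched_a),
        unmatched_b=sorted(set(sig_b.clusters()) - matched_b),
    )
    logger.info("marker_match %s-%s: %d marker links, %d/%d clusters unmatched",
                sig_a.stage, sig_b.stage, len(table),
                len(result.unmatched_a), len(sig_a.clusters()))
    return result
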
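"""End-to-end orchestration: wiring the stage modules into the full analysis.

These helpers run the canonical order — QC, normalization, per-stage
feature selection and clustering, signatures, cross-stage matching,
diversity and birth-order statistics — on one dataset.  They are thin
compositions of the module functions; the CLI and the reproduction script
call them rather than re-plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment, embed_2d, graph_cluster
from .diffexpr import SignatureSet, cluster_signatures
from .diversity import (
    DiversityReport,
    bootstrap_ci,
    cell_level_similarity,
    cluster_level_similarity,
)
from .features import FeatureSet, icim_select, overdispersed_genes
from .io_core import (
    EXCITATORY_LINEAGES,
    ExpressionDataset,
    PipelineConfig,
    logger,
    stage_sort_key,
)
from .matching import MatchResult, signature_match
from .preprocess import QCParams, cpm_normalize, filter_min_reads, filter_neuronal


def preprocess_all(dataset: ExpressionDataset, config: PipelineConfig) -> ExpressionDataset:
    """Read-depth filter, CPM/log normalization, neuronal marker filter."""
    params = QCParams(min_reads=config.min_reads,
                      marker_min_expr=config.marker_min_expr,
                      marker_min_count=config.marker_min_count)
    out = filter_min_reads(dataset, params)
    out = cpm_normalize(out)
    return filter_neuronal(out, params)


@dataclass
class StageAnalysis:
    """Per-stage feature set, clustering, and signature sets."""

    stage: str
    dataset: ExpressionDataset
    features: FeatureSet
    labels: ClusterAssignment
    signatures: SignatureSet


def analyze_stage(
    dataset: ExpressionDataset,
    stage: str,
    config: PipelineConfig,
    *,
    feature_method: str = "overdispersed",
    exclude_lineages: tuple[str, ...] = (),
    features: FeatureSet | None = None,
) -> StageAnalysis:
    """Cluster one stage's cells and compute cluster signatures.

    ``features`` supplies a precomputed (typically shared all-stage)
    feature set; informative genes found where types are most distinct
    carry type identity at stages where they are weaker, so a shared set
    clusters off-peak stages better than per-stage selection.
    """
    sub = dataset.subset_stage(stage)
    if exclude_lineages:
        sub = sub.subset_cells(~sub.cells["lineage"].isin(exclude_lineages).to_numpy())
    if features is not None:
        pass
    elif feature_method == "icim":
        features = icim_select(sub, min_cells=config.icim_min_cells,
                               max_depth=config.icim_max_depth, seed=config.seed,
                               min_markers=config.icim_min_markers,
                               alpha=config.de_alpha)
    else:
        features = overdispersed_genes(sub, n_top=config.n_top_overdispersed,
                                       n_bins=config.n_dispersion_bins)
    labels = graph_cluster(sub, features, resolution=config.resolution,
                           seed=config.seed, k=min(config.knn_k, sub.n_cells - 1))
    signatures = cluster_signatures(sub, labels.labels, alpha=config.de_alpha, stage=stage)
    return StageAnalysis(stage=stage, dataset=sub, features=features,
                         labels=labels, signatures=signatures)


def run_cross_stage(
    dataset: ExpressionDataset,
    config: PipelineConfig,
    *,
    exclude_lineages: tuple[str, ...] = ("vPN", "APL"),
) -> dict[str, StageAnalysis]:
    """Per-stage analyses on one shared all-stage feature set.

    Inhibitory populations are excluded (as when matching the excitatory
    types across stages); informative genes are selected once over every
    stage's cells and reused at each stage.
    """
    exc = dataset.subset_cells(
        ~dataset.cells["lineage"].isin(exclude_lineages).to_numpy())
    shared = overdispersed_genes(exc, n_top=config.n_top_overdispersed,
                                 n_bins=config.n_dispersion_bins)
    stages = stage_sort_key(exc.cells["stage"].dropna().unique(), exc.stage_order)
    return {s: analyze_stage(exc, s, config, features=shared) for s in stages}


def adjacent_stage_matches(
    analyses: dict[str, StageAnalysis],
    stage_order,
) -> list[MatchResult]:
    """Signature-match every adjacent stage pair, in stage order."""
    stages = stage_sort_key(list(analyses), stage_order)
    return [signature_match(analyses[a].signatures, analyses[b].signatures)
            for a, b in zip(stages[:-1], stages[1:])]


def majority_truth_types(labels: np.ndarray, truth_types: pd.Series) -> dict[int, str]:
    """Map each non-noise cluster to the planted type of most of its cells."""
    out = {}
    for c in np.unique(labels[labels >= 0]):
        vals = truth_types[labels == c]
        out[int(c)] = vals.mode().iloc[0]
    return out


def match_accuracy(
    match: MatchResult,
    analysis_a: StageAnalysis,
    analysis_b: StageAnalysis,
) -> dict:
    """Score two-way matches against planted cross-stage type identity.

    A two-way match is *correct* when the two clusters' majority planted
    types coincide; recovery is counted over planted types present as a
    majority type at both stages.
    """
    maj_a = majority_truth_types(analysis_a.labels.labels,
                                 analysis_a.dataset.cells["type_label"])
    maj_b = majority_truth_types(analysis_b.labels.labels,
                                 analysis_b.dataset.cells["type_label"])
    shared_types = set(maj_a.values()) & set(maj_b.values())
    pairs = match.two_way()
    correct = {maj_a[a] for a, b in pairs if maj_a.get(a) == maj_b.get(b)}
    n_false = sum(1 for a, b in pairs if maj_a.get(a) != maj_b.get(b))
    return {
        "n_planted": len(shared_types),
        "n_two_way": len(pairs),
        "n_recovered": len(correct & shared_types),
        "n_false": n_false,
        "recovery": len(correct & shared_types) / len(shared_types) if shared_types else np.nan,
        "false_rate": n_false / len(pairs) if pairs else 0.0,
    }


def diversity_by_stage(
    dataset: ExpressionDataset,
    config: PipelineConfig,
    *,
    lineages: tuple[str, ...] = EXCITATORY_LINEAGES,
    features: FeatureSet | None = None,
    embed_method: str = "pcs",
    analyses: dict[str, StageAnalysis] | None = None,
) -> DiversityReport:
    """Cell- and cluster-level similarity per (stage, lineage).

    Cell level: every cell's mean inverse Euclidean distance to the other
    cells of its (stage, lineage) subset, averaged.  The default space is
    the denoised feature space (the shared feature set reduced to 30 PCs,
    ``"pcs"``): inter-cell distances there track expression-space
    distances, so the statistic is comparable across stages.  2-D layouts
    (``"pca"``, ``"umap"``, ``"tsne"``) are offered for parity with
    visualization-driven workflows, with the caveat that planar
    projections distort the statistic — neighbourhood layouts equalize
    cluster spacing, and 2-PC projections are dominated by whichever
    variance direction survives the projection.  Cluster level: mean
    centroid Pearson correlation over that stage's clusters (from
    ``analyses``), restricted to one shared DE gene set — the signature
    union of the stage whose clusters are most distinct (largest union) —
    so every stage is compared on the same informative genes.
    """
    if features is None:
        features = overdispersed_genes(dataset, n_top=config.n_top_overdispersed,
                                       n_bins=config.n_dispersion_bins)
    stages = stage_sort_key(dataset.cells["stage"].dropna().unique(), dataset.stage_order)
    de_union: list[str] = []
    if analyses:
        unions = {s: sorted({g for sig in a.signatures.signatures.values() for g in sig})
                  for s, a in analyses.items()}
        de_union = max(unions.values(), key=len)
    rows = []
    for stage in stages:
        analysis = None
        if analyses is not None and stage in analyses:
            analysis = analyses[stage]
        for lineage in lineages:
            mask = ((dataset.cells["stage"] == stage)
                    & (dataset.cells["lineage"] == lineage)).to_numpy()
            sub = dataset.subset_cells(mask)
            if sub.n_cells < 3:
                continue
            if embed_method == "pcs":
                from .cluster import _feature_matrix, _prereduce

                coords = _prereduce(_feature_matrix(sub, features), config.seed)
                cell_sim = cell_level_similarity(coords)
            else:
                emb = embed_2d(sub, features, method=embed_method, seed=config.seed)
                cell_sim = cell_level_similarity(emb)
            n_clusters = np.nan
            cl_mean, ci = np.nan, (np.nan, np.nan)
            if analysis is not None:
                lin_mask = (analysis.dataset.cells["lineage"] == lineage).to_numpy()
                labels = analysis.labels.labels[lin_mask]
                sub_stage = analysis.dataset.subset_cells(lin_mask)
                ids = np.unique(labels[labels >= 0])
                sizes = [int((labels == c).sum()) for c in ids]
                keep_ids = [c for c, s in zip(ids, sizes) if s >= 2]
                if len(keep_ids) >= 2 and de_union:
                    labels = np.where(np.isin(labels, keep_ids), labels, -1)
                    cl = cluster_level_similarity(sub_stage, labels, de_union,
                                                  n_bootstrap=config.n_bootstrap,
                                                  seed=config.seed)
                    n_clusters = len(keep_ids)
                    cl_mean, ci = cl.mean, cl.ci
            rows.append({
                "stage": stage, "lineage": lineage, "n_cells": sub.n_cells,
                "cell_mean": cell_sim.mean, "cell_sd": cell_sim.sd,
                "n_clusters": n_clusters, "cluster_mean": cl_mean,
                "ci_low": ci[0], "ci_high": ci[1],
            })
    return DiversityReport(table=pd.DataFrame(rows))
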
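"""Per-stage dimensionality reduction and unsupervised clustering.

Cells are embedded in two dimensions (UMAP by default; a tSNE-style
embedding is available behind the same interface) on a selected feature
set, then clustered either by hierarchical density-based clustering
(HDBSCAN) on the embedding or, independently, by Leiden community
detection on a k-nearest-neighbour graph built in feature space.  Noise
cells receive label -1 and are excluded from signatures, matching and
similarity statistics downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import igraph
import leidenalg
import sklearn.cluster
import sklearn.decomposition
import sklearn.manifold
import sklearn.metrics
import sklearn.neighbors

from .features import FeatureSet
from .io_core import ExpressionDataset, ValidationError, logger

#: Feature-space dimensionality is reduced to this many PCs before
#: neighbour searches and embeddings (skipped when fewer features).
N_PCS_PREREDUCE = 30


@dataclass
class Embedding:
    """2-D per-cell coordinates from a manifold-learning method."""

    coords: np.ndarray  # (n_cells, 2)
    cell_ids: list[str]
    method: str  # "umap" | "tsne"
    features: list[str]
    seed: int

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"embedding": pd.DataFrame(
            {"cell_id": self.cell_ids, "x": self.coords[:, 0], "y": self.coords[:, 1]})}


@dataclass
class ClusterAssignment:
    """Per-cell integer labels; -1 is noise/unassigned."""

    labels: np.ndarray
    cell_ids: list[str]
    method: str
    params: dict = field(default_factory=dict)

    def n_clusters(self) -> int:
        return int(np.unique(self.labels[self.labels >= 0]).size)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"labels": pd.DataFrame({"cell_id": self.cell_ids, "cluster": self.labels})}

    def summary(self) -> dict:
        return {"method": self.method, "n_clusters": self.n_clusters(),
                "n_noise": int((self.labels < 0).sum()), **self.params}


def _feature_matrix(dataset: ExpressionDataset, features: FeatureSet) -> np.ndarray:
    if not features.genes:
        raise ValidationError("feature set is empty")
    idx = dataset.gene_index(features.genes)
    return dataset.require_logcpm()[idx, :].T  # cells x features


def _prereduce(X: np.ndarray, seed: int) -> np.ndarray:
    n_comp = min(N_PCS_PREREDUCE, X.shape[0] - 1, X.shape[1])
    if n_comp < 2 or X.shape[1] <= N_PCS_PREREDUCE:
        return X
    pca = sklearn.decomposition.PCA(n_components=n_comp, svd_solver="randomized",
                                    random_state=seed)
    return pca.fit_transform(X)


def embed_2d(
    dataset: ExpressionDataset,
    features: FeatureSet,
    method: str = "umap",
    seed: int = 0,
) -> Embedding:
    """Project cells into 2-D on the feature-set expression matrix.

    ``method`` is ``"umap"`` or ``"tsne"`` (neighbourhood-preserving
    layouts for visualization and density clustering; feature space is
    first reduced to 30 PCs) or ``"pca"`` (the top two principal
    components — a linear, distance-preserving projection, appropriate
    when inter-cell distances in the plane must track expression-space
    distances).  Deterministic for a fixed (data, features, seed).
    """
    X = _feature_matrix(dataset, features)
    if X.shape[0] < 3:
        raise ValidationError("need >= 3 cells to embed")
    if np.allclose(X.var(axis=0), 0):
        warnings.warn("degenerate input: all cells identical in feature space")
    if method == "pca":
        pca = sklearn.decomposition.PCA(n_components=2, svd_solver="randomized",
                                        random_state=seed)
        coords = pca.fit_transform(X)
        return Embedding(coords=np.asarray(coords, dtype=float),
                         cell_ids=list(dataset.cell_ids), method=method,
                         features=list(features.genes), seed=seed)
    Xr = _prereduce(X, seed)
    if method == "umap":
        import umap  # deferred: numba compilation cost on import

        n_neighbors = int(min(15, max(2, X.shape[0] - 1)))
        model = umap.UMAP(n_components=2, n_neighbors=n_neighbors, min_dist=0.3,
                          random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = model.fit_transform(Xr)
    elif method == "tsne":
        perplexity = min(30.0, max(2.0, (X.shape[0] - 1) / 3.0))
        model = sklearn.manifold.TSNE(n_components=2, random_state=seed, init="pca",
                                      perplexity=perplexity)
        coords = model.fit_transform(Xr)
    else:
        raise ValidationError(f"unknown embedding method {method!r}")
    return Embedding(coords=np.asarray(coords, dtype=float), cell_ids=list(dataset.cell_ids),
                     method=method, features=list(features.genes), seed=seed)


def density_cluster(
    embedding: Embedding,
    min_cluster_size: int = 15,
    min_samples: int | None = None,
) -> ClusterAssignment:
    """HDBSCAN on the 2-D embedding; noise cells get label -1."""
    if min_cluster_size < 2:
        raise ValidationError("min_cluster_size must be >= 2")
    model = sklearn.cluster.HDBSCAN(min_cluster_size=min_cluster_size,
                                    min_samples=min_samples, copy=True)
    labels = model.fit_predict(embedding.coords)
    labels = _densify_labels(labels)
    logger.info("density_cluster: %d clusters, %d noise cells",
                np.unique(labels[labels >= 0]).size, int((labels < 0).sum()))
    return ClusterAssignment(labels=labels, cell_ids=list(embedding.cell_ids),
                             method="hdbscan",
                             params={"min_cluster_size": min_cluster_size,
                                     "min_samples": min_samples})


def graph_cluster(
    dataset: ExpressionDataset,
    features: FeatureSet,
    resolution: float = 1.0,
    seed: int = 0,
    *,
    k: int = 15,
) -> ClusterAssignment:
    """Leiden community detection on the kNN graph in feature space."""
    X = _feature_matrix(dataset, features)
    n = X.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than n_cells={n}")
    Xr = _prereduce(X, seed)
    nn = sklearn.neighbors.NearestNeighbors(n_neighbors=k + 1).fit(Xr)
    _, idx = nn.kneighbors(Xr)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    graph = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    labels = _densify_labels(np.array(part.membership, dtype=int))
    logger.info("graph_cluster: %d communities (resolution %.2f)",
                np.unique(labels).size, resolution)
    return ClusterAssignment(labels=labels, cell_ids=list(dataset.cell_ids),
                             method="leiden",
                             params={"resolution": resolution, "k": k, "seed": seed})


def _densify_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel non-noise clusters to 0..k-1 by decreasing size (ties by old id)."""
    labels = np.asarray(labels, dtype=int).copy()
    ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    order = np.lexsort((ids, -counts))
    mapping = {int(ids[j]): rank for rank, j in enumerate(order)}
    out = labels.copy()
    for old, new in mapping.items():
        out[labels == old] = new
    return out


def agreement_ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same cells."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError("labelings must cover the same cell set")
    return float(sklearn.metrics.adjusted_rand_score(a, b))
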
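"""Similarity statistics, birth-order covariation test, dendrograms."""

import itertools

import numpy as np
import pandas as pd
import pytest

import pnatlas as pa
from pnatlas.cluster import Embedding
from pnatlas.io_core import ValidationError

from conftest import make_dataset


def embedding_from(coords):
    coords = np.asarray(coords, dtype=float)
    return Embedding(coords=coords, cell_ids=[f"c{i}" for i in range(len(coords))],
                     method="test", features=[], seed=0)


class TestCellLevelSimilarity:
    def test_two_points_at_distance_two(self):
        res = pa.cell_level_similarity(embedding_from([[0, 0], [2, 0]]))
        assert np.allclose(res.values, [0.5, 0.5])

    def test_collinear_points(self):
        res = pa.cell_level_similarity(embedding_from([[0, 0], [1, 0], [2, 0]]))
        assert np.allclose(res.values, [0.75, 1.0, 0.75])

    def test_homogeneity_under_rescaling(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 2))
        base = pa.cell_level_similarity(embedding_from(pts))
        scaled = pa.cell_level_similarity(embedding_from(3.0 * pts))
        assert np.allclose(scaled.values, base.values / 3.0)

    def test_coincident_pairs_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="coincident"):
            res = pa.cell_level_similarity(
                embedding_from([[0, 0], [0, 0], [1, 0]]))
        assert res.n_zero_pairs == 1
        assert np.allclose(res.values, [1.0, 1.0, 1.0])

    def test_subset_restriction(self):
        emb = embedding_from([[0, 0], [2, 0], [100, 0]])
        res = pa.cell_level_similarity(emb, cells=["c0", "c1"])
        assert np.allclose(res.values, [0.5, 0.5])


def crafted_centroid_dataset(centroids, n_per_cluster=3):
    """Dataset whose per-cluster mean logcpm over 'de genes' is given."""
    C = np.asarray(centroids, dtype=float)
    n_clusters, n_genes = C.shape
    n_cells = n_clusters * n_per_cluster
    ds = make_dataset(np.ones((n_genes, n_cells), dtype=int))
    labels = np.repeat(np.arange(n_clusters), n_per_cluster)
    pa.cpm_normalize(ds)
    ds.logcpm = C.T[:, labels].astype(float)
    return ds, labels


class TestClusterLevelSimilarity:
    def test_identical_centroids_correlate_perfectly(self):
        ds, labels = crafted_centroid_dataset([[1, 2, 3], [1, 2, 3]])
        res = pa.cluster_level_similarity(ds, labels, ["g0", "g1", "g2"],
                                          n_bootstrap=10)
        assert res.mean == pytest.approx(1.0)

    def test_reversed_centroids_anticorrelate(self):
        ds, labels = crafted_centroid_dataset([[1, 2, 3], [3, 2, 1]])
        res = pa.cluster_level_similarity(ds, labels, ["g0", "g1", "g2"],
                                          n_bootstrap=10)
        assert res.mean == pytest.approx(-1.0)

    def test_affine_invariance(self):
        ds, labels = crafted_centroid_dataset([[1, 2, 3], [2, 4, 6]])
        res = pa.cluster_level_similarity(ds, labels, ["g0", "g1", "g2"],
                                          n_bootstrap=10)
        assert res.mean == pytest.approx(1.0)

    def test_constant_centroid_excluded_with_warning(self):
        ds, labels = crafted_centroid_dataset([[1, 2, 3], [5, 5, 5], [3, 2, 1]])
        with pytest.warns(UserWarning, match="constant"):
            res = pa.cluster_level_similarity(ds, labels, ["g0", "g1", "g2"],
                                              n_bootstrap=10)
        assert res.pair_values.size == 1  # only the non-constant pair


class TestBootstrapCi:
    def test_constant_values_degenerate_interval(self):
        lo, hi = pa.bootstrap_ci([2.0, 2.0, 2.0], n_iter=100, seed=0)
        assert lo == hi == 2.0

    def test_default_iteration_count_is_one_thousand(self):
        import inspect
        assert inspect.signature(pa.bootstrap_ci).parameters["n_iter"].default == 1000

    def test_coverage_of_normal_mean(self):
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(200):
            sample = rng.normal(0, 1, size=100)
            lo, hi = pa.bootstrap_ci(sample, n_iter=300, seed=rep)
            hits += lo <= 0 <= hi
        assert 0.90 <= hits / 200 <= 0.99

    def test_single_value_warns(self):
        with pytest.warns(UserWarning):
            lo, hi = pa.bootstrap_ci([3.0], n_iter=10, seed=0)
        assert lo == hi == 3.0


# ---------------------------------------------------------------------------
# Birth-order statistic and permutation test
# ---------------------------------------------------------------------------

def _midranks(values):
    order = sorted(range(len(values)), key=lambda k: values[k])
    ranks = [0.0] * len(values)
    k = 0
    while k < len(order):
        m = k
        while m + 1 < len(order) and values[order[m + 1]] == values[order[k]]:
            m += 1
        avg = (k + m) / 2.0 + 1.0
        for t in range(k, m + 1):
            ranks[order[t]] = avg
        k = m + 1
    return ranks


def birth_order_oracle(C, ranks, min_group=5):
    """Independent re-implementation with explicit rank sorting."""
    C = np.asarray(C, dtype=float)
    ranks = list(ranks)
    n = len(ranks)
    rhos = []
    for i in range(n):
        earlier = [j for j in range(n) if ranks[j] < ranks[i]]
        later = [j for j in range(n) if ranks[j] > ranks[i]]
        group = earlier if len(earlier) >= len(later) else later
        if len(group) < min_group:
            continue
        sims = [C[i, j] for j in group]
        neg_dist = [-abs(ranks[j] - ranks[i]) for j in group]
        rs, rd = _midranks(sims), _midranks(neg_dist)
        ms, md = sum(rs) / len(rs), sum(rd) / len(rd)
        num = sum((a - ms) * (b - md) for a, b in zip(rs, rd))
        den = (sum((a - ms) ** 2 for a in rs) * sum((b - md) ** 2 for b in rd)) ** 0.5
        rhos.append(0.0 if den == 0 else num / den)
    if not rhos:
        raise ValueError("no eligible type")
    return sum(rhos) / len(rhos)


def birth_ordered_matrix(n, decay=0.1):
    """Similarity strictly decreasing with birth distance for every type."""
    idx = np.arange(n)
    return 1.0 - decay * np.abs(idx[:, None] - idx[None, :]) / n


class TestBirthOrderStat:
    def test_perfect_concordance_scores_one(self):
        C = birth_ordered_matrix(8)
        ranks = np.arange(1, 9)
        assert pa.birth_order_stat(C, ranks) == pytest.approx(1.0)

    def test_null_matrices_average_near_zero(self):
        rng = np.random.default_rng(0)
        stats = []
        for _ in range(100):
            A = rng.normal(size=(10, 10))
            C = np.corrcoef(A)
            stats.append(pa.birth_order_stat(C, rng.permutation(np.arange(1, 11))))
        assert abs(np.mean(stats)) < 0.05

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(7, 14))
            A = rng.normal(size=(n, n + 2))
            C = np.corrcoef(A)
            ranks = rng.permutation(np.arange(1, n + 1))
            assert pa.birth_order_stat(C, ranks) == pytest.approx(
                birth_order_oracle(C, ranks), abs=1e-12)

    def test_group_too_small_skips_and_empty_errors(self):
        C = birth_ordered_matrix(4)
        with pytest.raises(ValidationError):
            pa.birth_order_stat(C, np.arange(1, 5), min_group=5)

    def test_default_min_group_is_five(self):
        import inspect
        sig = inspect.signature(pa.birth_order_stat)
        assert sig.parameters["min_group"].default == 5


class TestBirthOrderPermutation:
    def test_default_iterations_five_thousand(self):
        import inspect
        sig = inspect.signature(pa.birth_order_permutation)
        assert sig.parameters["n_iter"].default == 5000

    def test_ordered_matrix_rejects_null(self):
        C = birth_ordered_matrix(8)
        res = pa.birth_order_permutation(C, np.arange(1, 9), n_iter=500, seed=0)
        assert res.p_value < 0.01

    def test_observed_at_maximum_gives_p_zero(self):
        C = birth_ordered_matrix(8)
        res = pa.birth_order_permutation(C, np.arange(1, 9), n_iter=200, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_value == 0.0  # strict-greater counting rule

    def test_plus_one_correction_optional(self):
        C = birth_ordered_matrix(8)
        res = pa.birth_order_permutation(C, np.arange(1, 9), n_iter=200, seed=0,
                                         plus_one_correction=True)
        assert res.p_value == pytest.approx(1 / 201)

    def test_sampled_p_agrees_with_full_enumeration(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(7, 9))
        C = np.corrcoef(A)
        C += 0.5 * birth_ordered_matrix(7)  # partial signal, non-trivial p
        ranks = np.arange(1, 8)
        null = pa.enumerate_birth_order_null(C, ranks)
        obs = pa.birth_order_stat(C, ranks)
        p_exact = float(np.mean(null > obs))
        res = pa.birth_order_permutation(C, ranks, n_iter=2000, seed=1)
        se = np.sqrt(p_exact * (1 - p_exact) / 2000)
        assert abs(res.p_value - p_exact) <= 3 * se + 1e-9

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValidationError):
            pa.birth_order_permutation(birth_ordered_matrix(8),
                                       np.arange(1, 9), n_iter=0, seed=0)


@pytest.fixture(scope="module")
def stage1_matrix():
    ds, truth = pa.simulate(pa.SimConfig(seed=0), only_stages=("P0",))
    pa.cpm_normalize(ds)
    sub = ds.subset_lineage("adPN")
    return pa.type_correlation_matrix(sub)


class TestTypeCorrelationMatrix:

    def test_diagonal_is_one_and_symmetric(self, stage1_matrix):
        corr, _ = stage1_matrix
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T)

    def test_rows_sorted_by_birth_rank(self, stage1_matrix):
        _, ranks = stage1_matrix
        assert (np.diff(ranks) > 0).all()

    def test_adjacent_types_correlate_more_than_distant(self):
        """Planted early gradient: near-birth-order types are more similar."""
        wins = 0
        for seed in range(10):
            ds, _ = pa.simulate(pa.SimConfig(seed=seed), only_stages=("P0",))
            pa.cpm_normalize(ds)
            corr, ranks = pa.type_correlation_matrix(ds.subset_lineage("adPN"))
            C = corr.to_numpy()
            n = len(ranks)
            adj = [C[i, i + 1] for i in range(n - 1)]
            far = [C[i, j] for i in range(n) for j in range(n) if j - i >= 5]
            wins += np.mean(adj) > np.mean(far)
        assert wins >= 9

    def test_n_pcs_capped_with_warning(self):
        ds, _ = pa.simulate(pa.SimConfig(seed=0), only_stages=("P0",))
        pa.cpm_normalize(ds)
        with pytest.warns(UserWarning, match="capped"):
            corr, _ = pa.type_correlation_matrix(ds.subset_lineage("lPN"), n_pcs=50)
        assert corr.shape == (10, 10)


# ---------------------------------------------------------------------------
# Dendrograms
# ---------------------------------------------------------------------------

class TestDendrogram:
    def test_two_profiles_single_join_at_their_distance(self):
        profiles = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        Z, leaves, newick = pa.dendrogram_order(profiles)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(5.0)
        assert set(leaves) == {"a", "b"}

    def test_closest_pair_joins_first(self):
        # mutual distances (ab)=1, (ac)=(bc)=5
        profiles = pd.DataFrame([[0.0], [1.0], [5.0]], index=["a", "b", "c"])
        Z, leaves, _ = pa.dendrogram_order(profiles)
        assert Z[0, 2] == pytest.approx(1.0)   # a-b join first
        assert Z[1, 2] == pytest.approx(5.0)   # complete linkage: max(4, 5)

    def test_leaf_order_invariant_to_row_order(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        profiles = pd.DataFrame(X, index=[f"k{i}" for i in range(6)])
        _, leaves_a, _ = pa.dendrogram_order(profiles)
        perm = rng.permutation(6)
        _, leaves_b, _ = pa.dendrogram_order(profiles.iloc[perm])
        assert leaves_a == leaves_b or leaves_a == leaves_b[::-1]

    def test_complete_linkage_matches_naive_agglomeration(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            X = rng.normal(size=(n, 3))
            profiles = pd.DataFrame(X, index=[str(i) for i in range(n)])
            Z, _, _ = pa.dendrogram_order(profiles)
            assert np.allclose(np.sort(Z[:, 2]),
                               complete_linkage_oracle(X), atol=1e-9)

    def test_newick_is_well_formed(self):
        profiles = pd.DataFrame(np.eye(4), index=list("abcd"))
        _, _, newick = pa.dendrogram_order(profiles)
        from io import StringIO
        from Bio import Phylo
        tree = Phylo.read(StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("abcd")


def complete_linkage_oracle(X):
    """Naive agglomerative complete linkage; returns sorted join heights."""
    clusters = [[i] for i in range(len(X))]
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return np.sort(heights)
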
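"""Jaccard similarity, reciprocal-best signature matching, marker matching."""

import numpy as np
import pytest

import pnatlas as pa
from pnatlas.cluster import ClusterAssignment
from pnatlas.diffexpr import SignatureSet
from pnatlas.matching import marker_match

from conftest import make_dataset


class TestJaccard:
    def test_identical_sets_score_one(self):
        assert pa.jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert pa.jaccard({"a"}, {"b"}) == 0.0

    def test_half_overlap(self):
        assert pa.jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_both_empty_defined_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert pa.jaccard(set(), set()) == 0.0


def signature_family(overlaps, size=10, prefix=("a", "b")):
    """Build two signature families realizing exact pairwise intersections.

    ``overlaps[i][j]`` tokens are shared between cluster i of family A and
    cluster j of family B; sets are padded with private tokens to ``size``
    so the Jaccard argmax pattern equals the overlap-count pattern.
    """
    n_a, n_b = len(overlaps), len(overlaps[0])
    a_sets = [set() for _ in range(n_a)]
    b_sets = [set() for _ in range(n_b)]
    for i in range(n_a):
        for j in range(n_b):
            shared = {f"s{i}{j}x{k}" for k in range(overlaps[i][j])}
            a_sets[i] |= shared
            b_sets[j] |= shared
    for sets, tag in ((a_sets, prefix[0]), (b_sets, prefix[1])):
        for idx, s in enumerate(sets):
            pad = {f"{tag}{idx}pad{k}" for k in range(size - len(s))}
            s |= pad
    sig_a = SignatureSet({i: sorted(s) for i, s in enumerate(a_sets)}, alpha=0.01,
                         stage="A")
    sig_b = SignatureSet({j: sorted(s) for j, s in enumerate(b_sets)}, alpha=0.01,
                         stage="B")
    return sig_a, sig_b


class TestSignatureMatch:
    def test_identical_families_all_two_way_at_one(self):
        sig_a, _ = signature_family([[6, 0], [0, 6]])
        res = pa.signature_match(sig_a, sig_a)
        assert res.two_way() == [(0, 0), (1, 1)]
        assert (res.pairs["jaccard"] == 1.0).all()

    def test_diagonal_dominant_matrix_gives_two_two_way(self):
        # mutual-argmax pattern of a [[high, low], [low, high]] matrix
        sig_a, sig_b = signature_family([[6, 1], [2, 5]])
        res = pa.signature_match(sig_a, sig_b)
        assert res.two_way() == [(0, 0), (1, 1)]
        assert set(res.pairs["match_class"]) == {"two_way"}

    def test_shared_best_column_yields_one_way_matches(self):
        # row argmaxes both point at b0; only (a0, b0) is mutual
        sig_a, sig_b = signature_family([[7, 5], [6, 1]])
        res = pa.signature_match(sig_a, sig_b)
        classes = dict(zip(zip(res.pairs["cluster_a"], res.pairs["cluster_b"]),
                           res.pairs["match_class"]))
        assert classes[(0, 0)] == "two_way"
        assert classes[(1, 0)] == "one_way_ab"
        assert classes[(0, 1)] == "one_way_ba"

    def test_argmax_tie_declares_no_match(self):
        sig_a, sig_b = signature_family([[4, 4]])
        res = pa.signature_match(sig_a, sig_b)
        assert res.two_way() == []
        assert not (res.pairs["match_class"] == "one_way_ab").any()

    def test_symmetry_under_stage_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            overlaps = rng.integers(0, 7, size=(3, 4)).tolist()
            sig_a, sig_b = signature_family(overlaps, size=12)
            fwd = pa.signature_match(sig_a, sig_b)
            rev = pa.signature_match(sig_b, sig_a)
            assert set(fwd.two_way()) == {(b, a) for a, b in rev.two_way()}
            fwd_ab = set(map(tuple, fwd.pairs.loc[
                fwd.pairs["match_class"] == "one_way_ab",
                ["cluster_a", "cluster_b"]].to_numpy()))
            rev_ba = set(map(tuple, rev.pairs.loc[
                rev.pairs["match_class"] == "one_way_ba",
                ["cluster_b", "cluster_a"]].to_numpy()))
            assert fwd_ab == rev_ba

    def test_empty_signature_cluster_excluded(self):
        sig_a, sig_b = signature_family([[6, 1], [2, 5]])
        sig_a.signatures[2] = []
        with pytest.warns(UserWarning, match="empty signatures"):
            res = pa.signature_match(sig_a, sig_b)
        assert 2 not in set(res.pairs["cluster_a"])


def crafted_marker_stage(expr_by_cluster, genes, lineages, n_per_cluster=6):
    """Dataset + labels + signatures where gene expression per cluster is
    given as logcpm levels (clusters x genes)."""
    expr = np.asarray(expr_by_cluster, dtype=float)
    n_clusters = expr.shape[0]
    n_cells = n_clusters * n_per_cluster
    ds = make_dataset(np.ones((len(genes), n_cells), dtype=int),
                      gene_ids=list(genes))
    labels = np.repeat(np.arange(n_clusters), n_per_cluster)
    ds.cells["lineage"] = [lineages[c] for c in labels]
    pa.cpm_normalize(ds)
    ds.logcpm = expr.T[:, labels].astype(float)
    sigs = SignatureSet({c: list(genes) for c in range(n_clusters)}, alpha=0.01)
    assign = ClusterAssignment(labels=labels, cell_ids=list(ds.cell_ids),
                               method="crafted")
    return ds, assign, sigs


class TestMarkerMatch:
    def test_unique_marker_links_clusters_of_same_lineage(self):
        #            gA   gB
        stage_a = [[8.0, 0.0],   # cluster 0: A only
                   [0.0, 8.0]]   # cluster 1: B only
        ds_a, lab_a, sig_a = crafted_marker_stage(stage_a, ["gA", "gB"],
                                                  ["adPN", "adPN"])
        ds_b, lab_b, sig_b = crafted_marker_stage(stage_a[::-1], ["gA", "gB"],
                                                  ["adPN", "adPN"])
        res = marker_match(ds_a, lab_a, sig_a, ds_b, lab_b, sig_b)
        assert (0, 1) in res.matched_pairs() and (1, 0) in res.matched_pairs()

    def test_marker_expressed_in_two_clusters_not_unique(self):
        stage = [[8.0, 8.0],
                 [8.0, 0.0]]  # gA expressed in both clusters
        ds, lab, sig = crafted_marker_stage(stage, ["gA", "gB"], ["adPN", "adPN"])
        res = marker_match(ds, lab, sig, ds, lab, sig)
        assert "gA" not in set(res.table["marker"])
        assert "gB" in set(res.table["marker"])  # unique to cluster 0

    def test_lineage_mismatch_is_not_a_match(self):
        stage = [[8.0, 0.0], [0.0, 8.0]]
        ds_a, lab_a, sig_a = crafted_marker_stage(stage, ["gA", "gB"],
                                                  ["adPN", "lPN"])
        ds_b, lab_b, sig_b = crafted_marker_stage(stage, ["gA", "gB"],
                                                  ["lPN", "adPN"])
        res = marker_match(ds_a, lab_a, sig_a, ds_b, lab_b, sig_b)
        assert res.matched_pairs() == []
        assert not res.table.empty  # links found but lineage-inconsistent

    def test_types_separable_only_by_gene_pair(self):
        """Two clusters share every single marker; only the conjunction
        A+ B+ vs A+ B- is unique."""
        #            gA   gB   gC
        stage = [[8.0, 8.0, 0.0],   # cluster 0: A+B+
                 [8.0, 0.0, 8.0]]   # cluster 1: A+C+
        ds, lab, sig = crafted_marker_stage(stage, ["gA", "gB", "gC"],
                                            ["adPN", "adPN"])
        res = marker_match(ds, lab, sig, ds, lab, sig)
        markers = set(res.table["marker"])
        assert "gA" not in markers            # shared, not unique
        assert "gA+gB" in markers             # pair selects cluster 0
        assert (0, 0) in res.matched_pairs() and (1, 1) in res.matched_pairs()


class TestMatchingRouteAgreement:
    def test_marker_and_signature_routes_agree_on_default_data(self):
        """On a default-condition stage pair, the two independent matching
        routes (unique markers, reciprocal-best Jaccard) agree on >= 90% of
        the cluster pairs either method matches."""
        from pnatlas import pipeline

        ds, _ = pa.simulate(pa.SimConfig(seed=0), only_stages=("P24", "P48"))
        config = pa.PipelineConfig(seed=0)
        ds = pipeline.preprocess_all(ds, config)
        analyses = pipeline.run_cross_stage(ds, config)
        a, b = analyses["P24"], analyses["P48"]
        sig_pairs = set(pa.signature_match(a.signatures, b.signatures).two_way())
        mm = marker_match(a.dataset, a.labels, a.signatures,
                          b.dataset, b.labels, b.signatures,
                          expr_threshold=config.expr_threshold,
                          frac_threshold=config.frac_threshold,
                          max_pair_search=config.max_pair_search)
        mk_pairs = set(mm.matched_pairs())
        assert sig_pairs and mk_pairs
        agreement = len(sig_pairs & mk_pairs) / len(sig_pairs | mk_pairs)
        assert agreement >= 0.90
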
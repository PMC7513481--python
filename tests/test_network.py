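"""Network data model: loading, normalization, pair counting, sampling,
and cross-validation splitting."""

import json

import numpy as np
import pytest

from dpddi.network import (
    DDINetwork,
    count_unlabeled_pairs,
    enumerate_unlabeled_pairs,
    load_edge_list,
    make_cv_splits,
    network_sparsity,
    normalize_adjacency,
    pair_sparsity,
    read_adjacency,
    sample_negatives,
    subnetwork_with_edges,
    unlabeled_pair_count,
    write_adjacency,
)


def _write(tmp_path, text, name="edges.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadEdgeList:
    def test_undirected_dedup(self, tmp_path):
        net = load_edge_list(_write(tmp_path, "a\tb\nb\ta\na\tc\n"))
        assert net.n_drugs == 3
        assert net.n_edges == 2

    def test_empty_file_errors(self, tmp_path):
        with pytest.raises(ValueError, match="no edges"):
            load_edge_list(_write(tmp_path, ""))

    def test_k3_complete_graph(self, tmp_path):
        net = load_edge_list(_write(tmp_path, "a,b\nb,c\na,c\n"))
        expected = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        np.testing.assert_array_equal(net.adjacency, expected)

    def test_self_pair_names_drug(self, tmp_path):
        with pytest.raises(ValueError, match="'x'"):
            load_edge_list(_write(tmp_path, "a\tb\nx\tx\n"))

    def test_malformed_row_reports_line(self, tmp_path):
        with pytest.raises(ValueError, match="line 2"):
            load_edge_list(_write(tmp_path, "a\tb\nonlyone\n"))

    def test_header_skipped_and_ids_sorted(self, tmp_path):
        net = load_edge_list(_write(tmp_path, "drug_id_1\tdrug_id_2\nz\ta\nm\tz\n"))
        assert net.drug_ids == ("a", "m", "z")
        assert net.n_edges == 2

    def test_index_order_independent_of_row_order(self, tmp_path):
        n1 = load_edge_list(_write(tmp_path, "b\ta\nc\tb\n", "e1.tsv"))
        n2 = load_edge_list(_write(tmp_path, "b\tc\na\tb\n", "e2.tsv"))
        assert n1.drug_ids == n2.drug_ids
        np.testing.assert_array_equal(n1.adjacency, n2.adjacency)


class TestNetworkInvariants:
    def test_rejects_asymmetric(self):
        A = np.array([[0, 1], [0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DDINetwork(("a", "b"), A)

    def test_rejects_nonzero_diagonal(self):
        A = np.array([[1, 1], [1, 0]])
        with pytest.raises(ValueError, match="diagonal"):
            DDINetwork(("a", "b"), A)

    def test_edge_count_matches_adjacency_sum(self, sbm30):
        assert len(sbm30.edges) == sbm30.adjacency.sum() // 2

    def test_adjacency_roundtrip(self, tmp_path, sbm30):
        path = tmp_path / "adj.tsv"
        write_adjacency(sbm30, path)
        back = read_adjacency(path)
        assert back.drug_ids == sbm30.drug_ids
        np.testing.assert_array_equal(back.adjacency, sbm30.adjacency)


class TestNormalizeAdjacency:
    def test_isolated_node_is_unit_self_loop(self):
        net = DDINetwork(("a",), np.zeros((1, 1)))
        np.testing.assert_array_equal(normalize_adjacency(net).matrix, [[1.0]])

    def test_two_node_single_edge(self, two_node):
        np.testing.assert_allclose(normalize_adjacency(two_node).matrix,
                                   [[0.5, 0.5], [0.5, 0.5]])

    def test_k3_entries_one_third(self, k3):
        np.testing.assert_allclose(normalize_adjacency(k3).matrix,
                                   np.full((3, 3), 1 / 3))

    @pytest.mark.parametrize("net", [
        DDINetwork.from_edges("abc", [(0, 1), (1, 2), (0, 2)]),                 # K3
        DDINetwork.from_edges("abcd", [(i, j) for i in range(4) for j in range(i + 1, 4)]),  # K4
        DDINetwork.from_edges("abcd", [(0, 1), (1, 2), (2, 3), (0, 3)]),         # 4-cycle
    ], ids=["K3", "K4", "C4"])
    def test_regular_graph_rows_sum_to_one(self, net):
        row_sums = normalize_adjacency(net).matrix @ np.ones(net.n_drugs)
        np.testing.assert_allclose(row_sums, 1.0, atol=1e-12)

    def test_symmetric_entries_in_unit_interval(self, sbm30):
        M = normalize_adjacency(sbm30).matrix
        np.testing.assert_allclose(M, M.T)
        assert (M >= 0).all() and (M <= 1).all()


class TestPairCounting:
    @pytest.mark.parametrize("m,e,expected", [
        (1562, 180576, 1_038_565),
        (548, 48584, 101_294),
    ])
    def test_unlabeled_count_from_database_sizes(self, m, e, expected):
        assert unlabeled_pair_count(m, e) == expected

    def test_complete_graph_has_no_unlabeled(self, k3):
        assert count_unlabeled_pairs(k3) == 0

    @pytest.mark.parametrize("m,e,pct", [(1562, 180576, 14.8), (548, 48584, 32.4)])
    def test_sparsity_from_database_sizes(self, m, e, pct):
        assert round(100 * pair_sparsity(m, e), 1) == pct

    def test_complete_graph_sparsity_100(self, k3):
        assert network_sparsity(k3) == 1.0

    def test_sparsity_needs_two_drugs(self):
        with pytest.raises(ValueError):
            pair_sparsity(1, 0)

    def test_unlabeled_plus_edges_is_all_pairs(self, sbm30, sbm200):
        for net in (sbm30, sbm200):
            m = net.n_drugs
            assert count_unlabeled_pairs(net) + net.n_edges == m * (m - 1) // 2


class TestSampleNegatives:
    def test_all_equals_brute_force_enumeration(self, sbm30):
        brute = {(i, j) for i in range(sbm30.n_drugs) for j in range(i + 1, sbm30.n_drugs)
                 if not sbm30.adjacency[i, j]}
        assert set(sample_negatives(sbm30, "all", seed=0)) == brute

    def test_ratio_one_count(self, sbm30):
        assert len(sample_negatives(sbm30, 1, seed=3)) == sbm30.n_edges

    def test_seed_reproducibility_and_variation(self, sbm200):
        a = sample_negatives(sbm200, 1, seed=5)
        b = sample_negatives(sbm200, 1, seed=5)
        c = sample_negatives(sbm200, 1, seed=6)
        assert a == b
        assert a != c

    def test_negatives_disjoint_from_positives(self, sbm30):
        pos = set(sbm30.edges)
        assert not pos & set(sample_negatives(sbm30, 2, seed=1))

    def test_oversampling_reports_both_counts(self, k3):
        with pytest.raises(ValueError, match="0 unlabeled"):
            sample_negatives(k3, 1, seed=0)


class TestCVSplits:
    def _plan(self, net, seed=0, ratio=1):
        return make_cv_splits(net, sample_negatives(net, ratio, seed), seed)

    def test_100_positives_fold_and_split_sizes(self):
        rng = np.random.default_rng(0)
        # a 102-drug ring plus chords: build an arbitrary 100-edge graph
        edges = set()
        while len(edges) < 100:
            i, j = sorted(rng.choice(60, size=2, replace=False))
            edges.add((int(i), int(j)))
        net = DDINetwork.from_edges([f"d{k:02d}" for k in range(60)], sorted(edges))
        plan = self._plan(net)
        assert [len(f) for f in plan.positive_folds] == [20] * 5
        for it in plan.iterations:
            assert len(it.test_pos) == 20
            assert len(it.train_pos) == 72
            assert len(it.val_pos) == 8

    def test_minimum_five_positives(self):
        net = DDINetwork.from_edges("abcdef", [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)])
        plan = self._plan(net)
        assert [len(f) for f in plan.positive_folds] == [1] * 5

    def test_fewer_than_five_positives_errors(self, k3):
        with pytest.raises(ValueError, match="at least 5"):
            make_cv_splits(k3, [], seed=0)

    def test_same_seed_identical_plan(self, sbm30):
        negs = sample_negatives(sbm30, 1, seed=9)
        p1 = make_cv_splits(sbm30, negs, seed=9)
        p2 = make_cv_splits(sbm30, negs, seed=9)
        assert p1.positive_folds == p2.positive_folds
        assert [it.train_pos for it in p1.iterations] == [it.train_pos for it in p2.iterations]

    def test_positive_side_independent_of_negative_count(self, sbm30):
        p1 = make_cv_splits(sbm30, sample_negatives(sbm30, 1, 4), seed=4)
        p2 = make_cv_splits(sbm30, sample_negatives(sbm30, 2, 4), seed=4)
        assert p1.positive_folds == p2.positive_folds
        assert [it.train_pos for it in p1.iterations] == [it.train_pos for it in p2.iterations]

    def test_negative_must_not_be_positive(self, sbm30):
        edge = sbm30.edges[0]
        with pytest.raises(ValueError, match="positive"):
            make_cv_splits(sbm30, [edge], seed=0)

    @pytest.mark.parametrize("seed", range(25))
    def test_plan_invariants(self, sbm30, seed):
        plan = self._plan(sbm30, seed=seed)
        positives = set(sbm30.edges)
        # folds partition positives with near-equal sizes
        fold_union = [p for f in plan.positive_folds for p in f]
        assert len(fold_union) == len(positives) and set(fold_union) == positives
        sizes = [len(f) for f in plan.positive_folds]
        assert max(sizes) - min(sizes) <= 1
        for it in plan.iterations:
            sets = [set(s) for s in it.all_sets()]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    assert not sets[a] & sets[b]
            heldin = len(it.train_pos) + len(it.val_pos)
            assert abs(len(it.train_pos) - 0.9 * heldin) <= 1

    def test_json_serialization(self, sbm30):
        plan = self._plan(sbm30)
        doc = json.loads(plan.to_json(sbm30.drug_ids))
        assert doc["seed"] == 0
        assert len(doc["positive_folds"]) == sbm30.n_edges
        key = next(iter(doc["positive_folds"]))
        assert "|" in key


def test_subnetwork_keeps_only_given_edges(sbm30):
    kept = sbm30.edges[:10]
    sub = subnetwork_with_edges(sbm30, kept)
    assert sub.drug_ids == sbm30.drug_ids
    assert set(sub.edges) == set(kept)


def test_enumerate_unlabeled_excludes_edges(sbm30):
    unlabeled = enumerate_unlabeled_pairs(sbm30)
    assert not set(unlabeled) & set(sbm30.edges)
    assert len(unlabeled) == count_unlabeled_pairs(sbm30)
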
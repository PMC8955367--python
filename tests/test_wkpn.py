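"""Propagation-number importance: analytic graphs, formula values,
invariants, and equivalence with the brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wkpnet import wkpn
from wkpnet.experiments import random_binary_network, wkpn_bruteforce

from conftest import make_network


class TestKOrderNumbers:
    def test_path_graph(self, path_abc):
        N, d = wkpn.k_order_numbers(path_abc)
        assert d == 2
        assert N[:, 0].tolist() == [1, 1, 1]
        assert N[:, 1].tolist() == [2, 3, 2]
        assert N[:, 2].tolist() == [3, 3, 3]

    def test_star_k1(self, star4):
        N, d = wkpn.k_order_numbers(star4)
        assert d == 2
        assert N[:, 1].tolist() == [4, 2, 2, 2]

    def test_edgeless_graph(self):
        net = make_network([], ("A", "B", "C"))
        N, d = wkpn.k_order_numbers(net)
        assert d == 0
        assert N[:, 0].tolist() == [1, 1, 1]

    def test_disconnected_distances_and_component_size(self):
        # two components: triangle + isolated edge
        net = make_network([("A", "B"), ("B", "C"), ("A", "C"), ("D", "E")],
                           ("A", "B", "C", "D", "E"))
        D = wkpn.shortest_path_lengths(net)
        assert np.isinf(D[0, 3])
        N, d = wkpn.k_order_numbers(net)
        assert d == 1
        # N[v, d] equals the size of v's connected component
        assert N[:, d].tolist() == [3, 3, 3, 2, 2]

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_k_and_component_bound(self, seed):
        rng = np.random.default_rng(seed)
        net = random_binary_network(rng)
        N, d = wkpn.k_order_numbers(net)
        assert (np.diff(N, axis=1) >= 0).all()
        assert (N >= 1).all() and (N <= net.n_nodes).all()


class TestStructureEntropy:
    def test_uniform_counts_reach_log_n(self):
        assert wkpn.structure_entropy(np.ones(5)) == pytest.approx(
            math.log(5), abs=1e-14)

    def test_path_k1_value(self):
        # direct evaluation for counts [2, 3, 2]
        p = np.array([2, 3, 2]) / 7
        expected = float(-(p * np.log(p)).sum())
        assert expected == pytest.approx(1.0790, abs=5e-5)
        assert wkpn.structure_entropy(np.array([2, 3, 2])) == pytest.approx(
            expected, abs=1e-14)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=1000), min_size=2,
                    max_size=40))
    def test_bounds_hold_for_any_count_vector(self, counts):
        h = wkpn.structure_entropy(np.array(counts))
        assert 0 < h <= math.log(len(counts)) + 1e-12
        if len(set(counts)) == 1:
            assert h == pytest.approx(math.log(len(counts)), abs=1e-12)

    def test_rejects_zero_counts(self):
        with pytest.raises(ValueError):
            wkpn.structure_entropy(np.array([0, 1, 2]))

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_binary_network(rng)
        N, d = wkpn.k_order_numbers(net)
        n = net.n_nodes
        for k in range(d + 1):
            h = wkpn.structure_entropy(N[:, k])
            assert 0 < h <= math.log(n) + 1e-12


class TestNodeImportance:
    @pytest.mark.parametrize("edges,labels", [
        # 4-cycle
        ([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")],
         ("A", "B", "C", "D")),
        # complete K4
        ([("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"),
          ("C", "D")], ("A", "B", "C", "D")),
    ])
    def test_vertex_transitive_graphs_uniform(self, edges, labels):
        prof = wkpn.node_importance(make_network(edges, labels))
        np.testing.assert_allclose(prof.Q, 1 / len(labels), atol=1e-14)

    def test_star_center_ranks_first(self, star4):
        prof = wkpn.node_importance(star4)
        assert prof.ranking[0] == "S"
        assert prof.Q[0] > prof.Q[1:].max()

    def test_q_conserved(self, path_abc, star4):
        for net in (path_abc, star4):
            prof = wkpn.node_importance(net)
            assert prof.Q.sum() == pytest.approx(1.0, abs=1e-12)

    def test_ties_broken_by_label(self):
        # all-equal scores on a cycle: ranking must be label-sorted
        net = make_network([("B", "A"), ("A", "C"), ("C", "B")],
                           ("B", "A", "C"))
        prof = wkpn.node_importance(net)
        assert prof.ranking == ("A", "B", "C")

    @pytest.mark.parametrize("seed", range(5))
    def test_relabeling_equivariance(self, seed):
        rng = np.random.default_rng(200 + seed)
        net = random_binary_network(rng)
        perm = rng.permutation(net.n_nodes)
        permuted = wkpn.BinaryNetwork(
            adjacency=net.adjacency[np.ix_(perm, perm)],
            node_labels=tuple(net.node_labels[i] for i in perm))
        q1 = wkpn.node_importance(net).Q
        q2 = wkpn.node_importance(permuted).Q
        np.testing.assert_allclose(q1[perm], q2, atol=1e-14)

    def test_single_node(self):
        prof = wkpn.node_importance(make_network([], ("A",)))
        assert prof.Q.tolist() == [1.0]

    def test_alternative_normalization_and_inverted_weights(self, star4):
        for kwargs in ({"normalization": "minmax"},
                       {"invert_weights": True}):
            prof = wkpn.node_importance(star4, **kwargs)
            assert sorted(prof.ranking) == sorted(star4.node_labels)
            assert np.isfinite(prof.Q).all()
        with pytest.raises(ValueError):
            wkpn.node_importance(star4, normalization="bogus")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        net = random_binary_network(rng)
        prof = wkpn.node_importance(net)
        ref = wkpn_bruteforce(net.adjacency)
        assert prof.d == ref["d"]
        np.testing.assert_allclose(prof.N, ref["N"], atol=0)
        np.testing.assert_allclose(prof.Q, ref["Q"], atol=1e-13)


class TestMarkNodes:
    def test_star_marks_only_center(self, star4):
        marked = wkpn.mark_nodes(wkpn.node_importance(star4), threshold=0.8)
        assert marked.marked == ("S",)
        assert marked.normalized_q.min() == 0.0
        assert marked.normalized_q.max() == 1.0

    def test_extreme_thresholds(self, star4):
        prof = wkpn.node_importance(star4)
        assert wkpn.mark_nodes(prof, threshold=1.0).marked == ()
        low = wkpn.mark_nodes(prof, threshold=0.0)
        assert set(low.marked) == {"S"}  # leaves sit exactly at min

    def test_constant_scores_warn(self):
        net = make_network([("A", "B"), ("B", "C"), ("C", "A")],
                           ("A", "B", "C"))
        with pytest.warns(UserWarning):
            marked = wkpn.mark_nodes(wkpn.node_importance(net))
        assert marked.marked == ()


class TestComparators:
    def test_wdc_star_and_complete(self, star4):
        assert wkpn.wdc(star4).tolist() == [3, 1, 1, 1]
        k4 = make_network([("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"),
                           ("B", "D"), ("C", "D")], ("A", "B", "C", "D"))
        assert wkpn.wdc(k4).tolist() == [3, 3, 3, 3]

    def test_wdc_equals_row_sums_on_weights(self):
        rng = np.random.default_rng(5)
        w = rng.random((6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        np.testing.assert_allclose(wkpn.wdc(w), w.sum(axis=1))

    def test_wpr_uniform_on_regular_graph(self):
        cycle = make_network([("A", "B"), ("B", "C"), ("C", "D"),
                              ("D", "A")], ("A", "B", "C", "D"))
        np.testing.assert_allclose(wkpn.wpr(cycle), 0.25, atol=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_wpr_matches_google_matrix_eigenvector(self, seed):
        rng = np.random.default_rng(400 + seed)
        n = int(rng.integers(3, 11))
        w = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        scores = wkpn.wpr(w, damping=0.85)
        assert scores.sum() == pytest.approx(1.0, abs=1e-8)
        # dense oracle: leading left eigenvector of the Google matrix
        strength = w.sum(axis=1)
        P = np.where(strength[:, None] > 0,
                     w / np.where(strength[:, None] == 0, 1,
                                  strength[:, None]),
                     1.0 / n)
        G = 0.85 * P + 0.15 / n
        vals, vecs = np.linalg.eig(G.T)
        lead = np.argmax(vals.real)
        pi = np.abs(vecs[:, lead].real)
        pi = pi / pi.sum()
        np.testing.assert_allclose(scores, pi, atol=1e-6)
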
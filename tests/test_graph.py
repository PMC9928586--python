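import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungmap import (cluster_graph, edge_weights, one_hot, optimal_paths,
                     prune, shared_edges, simulate_snn_graph,
                     transition_matrix)


def brute_force_shared_edges(adj: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Count every ordered adjacency entry between cluster pairs by loop."""
    clusters = np.unique(labels)
    pos = {c: i for i, c in enumerate(clusters)}
    e = np.zeros((len(clusters), len(clusters)), dtype=np.int64)
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                e[pos[labels[j]], pos[labels[i]]] += 1
    return e


def random_instance(rng, n_max=30, k_max=5):
    n = rng.integers(4, n_max + 1)
    k = rng.integers(2, k_max + 1)
    labels = rng.integers(0, k, size=n)
    upper = np.triu(rng.random((n, n)) < 0.3, k=1)
    adj = (upper | upper.T).astype(int)
    return adj, labels


class TestSharedEdges:
    def test_block_diagonal_pairs(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        adj[2, 3] = adj[3, 2] = 1
        o, _ = one_hot([0, 0, 1, 1])
        np.testing.assert_array_equal(shared_edges(adj, o),
                                      [[2, 0], [0, 2]])

    def test_single_cluster_counts_each_edge_twice(self):
        rng = np.random.default_rng(0)
        adj, _ = random_instance(rng)
        labels = np.zeros(adj.shape[0], dtype=int)
        o, _ = one_hot(labels)
        m = adj.sum() // 2
        np.testing.assert_array_equal(shared_edges(adj, o), [[2 * m]])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        adj, labels = random_instance(rng)
        o, _ = one_hot(labels)
        np.testing.assert_array_equal(shared_edges(adj, o),
                                      brute_force_shared_edges(adj, labels))

    def test_total_edge_conservation(self):
        rng = np.random.default_rng(5)
        adj, labels = random_instance(rng)
        o, _ = one_hot(labels)
        e = shared_edges(adj, o)
        assert e.sum() == adj.sum() == 2 * (adj.sum() // 2)
        np.testing.assert_array_equal(e, e.T)  # symmetric G => symmetric E

    def test_rejects_self_loops_and_asymmetry(self):
        o, _ = one_hot([0, 1])
        with pytest.raises(ValueError):
            shared_edges(np.array([[1, 0], [0, 0]]), o)
        with pytest.raises(ValueError):
            shared_edges(np.array([[0, 1], [0, 0]]), o)


class TestSharedEdgesProperties:
    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_conservation_and_symmetry_hold_for_any_instance(self, seed):
        rng = np.random.default_rng(seed)
        adj, labels = random_instance(rng)
        o, _ = one_hot(labels)
        e = shared_edges(adj, o)
        assert e.sum() == adj.sum()  # every ordered adjacency entry counted
        np.testing.assert_array_equal(e, e.T)
        p = transition_matrix(e)
        nz = e.sum(axis=1) > 0
        np.testing.assert_allclose(p[nz].sum(axis=1), 1.0, atol=1e-12)


class TestTransitionMatrix:
    def test_block_diagonal_gives_identity(self):
        np.testing.assert_allclose(transition_matrix([[2, 0], [0, 2]]),
                                   np.eye(2))

    def test_hand_normalized_example(self):
        p = transition_matrix([[4, 2], [2, 6]])
        np.testing.assert_allclose(p, [[2 / 3, 1 / 3], [0.25, 0.75]])

    def test_nonzero_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        e = rng.integers(0, 10, size=(5, 5))
        e[2] = 0
        p = transition_matrix(e)
        sums = p.sum(axis=1)
        np.testing.assert_allclose(sums[[0, 1, 3, 4]], 1.0, atol=1e-12)
        assert sums[2] == 0.0


class TestPrune:
    def test_strictly_below_threshold_removed(self):
        p = np.array([[5e-5, 1e-4], [0.5, 0.1]])
        out = prune(p, 1e-4)
        assert out[0, 0] == 0.0
        assert out[0, 1] == 1e-4  # boundary kept ("below" is strict)

    def test_zero_threshold_is_identity(self):
        p = np.array([[0.2, 0.8]])
        np.testing.assert_array_equal(prune(p, 0.0), p)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        p = rng.random((4, 4)) * 1e-3
        np.testing.assert_array_equal(prune(prune(p)), prune(p))

    def test_no_renormalization_by_default(self):
        p = np.array([[0.99995, 5e-5]])
        out = prune(p)
        assert out[0, 0] == 0.99995  # surviving p values preserved exactly

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            prune(np.eye(2), -1e-3)


class TestEdgeWeights:
    def test_inverse_probability(self):
        w = edge_weights(np.array([[0.5, 1.0], [0.0, 0.25]]))
        assert w[0, 0] == 2.0 and w[0, 1] == 1.0 and w[1, 1] == 4.0
        assert np.isinf(w[1, 0])  # p = 0 -> edge absent


class TestOptimalPaths:
    def test_root_equals_target(self):
        w = edge_weights(np.eye(3))
        out = optimal_paths(w, 0, [0])
        assert out[0] == {"path": [0], "weight": 0.0}

    def test_unreachable_target_reported_absent(self):
        w = np.full((3, 3), np.inf)
        out = optimal_paths(w, 0, [2])
        assert out[2] is None

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(3, 9)
        p = rng.random((k, k))
        p[rng.random((k, k)) < 0.4] = 0.0
        w = edge_weights(p)
        g = nx.DiGraph()
        g.add_nodes_from(range(k))
        for a in range(k):
            for b in range(k):
                if np.isfinite(w[a, b]) and a != b:
                    g.add_edge(a, b, weight=w[a, b])
        out = optimal_paths(w, 0, list(range(1, k)))
        for t in range(1, k):
            best = None
            for path in nx.all_simple_paths(g, 0, t):
                tw = sum(w[a, b] for a, b in zip(path, path[1:]))
                if best is None or tw < best - 1e-12:
                    best = tw
            if best is None:
                assert out[t] is None
            else:
                assert out[t]["weight"] == pytest.approx(best)

    def test_lexicographic_tie_break(self):
        # two equal-weight routes 0->1->3 and 0->2->3: path through 1 wins
        w = np.full((4, 4), np.inf)
        w[0, 1] = w[0, 2] = 1.0
        w[1, 3] = w[2, 3] = 1.0
        out = optimal_paths(w, 0, [3])
        assert out[3]["path"] == [0, 1, 3]

    def test_root_not_in_graph_raises(self):
        with pytest.raises(ValueError):
            optimal_paths(np.eye(2), 5, [0])


class TestPlantedChain:
    @pytest.mark.parametrize("seed", range(10))
    def test_chain_recovered_through_middle_cluster(self, seed):
        labels = np.repeat(["A", "B", "C"], 20)
        prob = np.array([[0.3, 0.05, 0.0],
                         [0.05, 0.3, 0.05],
                         [0.0, 0.05, 0.3]])
        adj = simulate_snn_graph(labels, prob, seed=seed)
        res = cluster_graph(adj, labels)
        out = optimal_paths(res["W"], "A", ["C"],
                            cluster_ids=list(res["clusters"]))
        assert out["C"]["path"] == ["A", "B", "C"]
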
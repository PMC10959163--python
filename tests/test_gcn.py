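"""GCN propagation, training determinism, and inference contracts."""

import numpy as np
import pytest

from mdgcn.gcn import (
    GCNConfig,
    TrainedModel,
    _subgraph_adjacency,
    gcn_layer,
    normalized_adjacency,
    predict_scores,
    train,
)
from mdgcn.pair_graph import PairGraph
from mdgcn.sampler import edge_probabilities, estimate_normalization, sample_subgraph
from mdgcn.similarity import InputError


def dense_oracle(n, edges, h, w):
    """Brute-force dense evaluation of D~^{-1/2}(A+I)D~^{-1/2} H W."""
    a = np.zeros((n, n))
    for u, v in edges:
        a[u, v] = a[v, u] = 1.0
    a += np.eye(n)
    d = np.diag(1.0 / np.sqrt(a.sum(1)))
    return d @ a @ d @ h @ w


def random_graph(rng, n, p=0.4):
    edges = [[i, j] for i in range(n) for j in range(i + 1, n) if rng.random() < p]
    e = np.array(edges, dtype=np.int64).reshape(-1, 2)
    return PairGraph(n_nodes=n, edges=e, weights=np.ones(len(e)))


class TestNormalizedAdjacency:
    def test_isolated_node_is_identity(self):
        g = PairGraph(n_nodes=1, edges=np.empty((0, 2)), weights=np.empty(0))
        np.testing.assert_allclose(normalized_adjacency(g).toarray(), [[1.0]])

    def test_two_node_edge(self, graph_factory):
        g = graph_factory(2, [[0, 1]])
        np.testing.assert_allclose(
            normalized_adjacency(g).toarray(), [[0.5, 0.5], [0.5, 0.5]]
        )

    def test_symmetric_and_regular_rows_sum_to_one(self, graph_factory):
        cycle = graph_factory(6, [[i, (i + 1) % 6] for i in range(6)])
        a = normalized_adjacency(cycle).toarray()
        np.testing.assert_allclose(a, a.T, atol=1e-15)
        np.testing.assert_allclose(a.sum(1), 1.0, atol=1e-12)


class TestGcnLayer:
    def test_identity_passthrough(self):
        h = np.random.default_rng(0).random((4, 3))
        out = gcn_layer(h, np.eye(4), np.eye(3), "identity")
        np.testing.assert_allclose(out, h)

    def test_two_node_hand_example(self, graph_factory):
        a = normalized_adjacency(graph_factory(2, [[0, 1]]))
        out = gcn_layer(np.eye(2), a, np.eye(2), "identity")
        np.testing.assert_allclose(out, [[0.5, 0.5], [0.5, 0.5]])

    def test_zero_weights_give_zero(self):
        h = np.ones((3, 2))
        out = gcn_layer(h, np.eye(3), np.zeros((2, 2)), "identity")
        assert (out == 0).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            gcn_layer(np.ones((3, 2)), np.eye(3), np.ones((3, 2)))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_dense_oracle_on_random_graphs(self, seed):
        """Sparse layer output equals the dense brute-force evaluation."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        g = random_graph(rng, n)
        h = rng.normal(size=(n, int(rng.integers(1, 5))))
        w = rng.normal(size=(h.shape[1], int(rng.integers(1, 4))))
        got = gcn_layer(h, normalized_adjacency(g), w, "relu")
        want = np.maximum(dense_oracle(n, g.edges, h, w), 0.0)
        np.testing.assert_allclose(got, want, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_subgraph_forward_matches_dense_restriction(self, seed):
        """Minibatch propagation equals dense evaluation of the induced subgraph."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 13))
        g = random_graph(rng, n, p=0.5)
        if g.n_edges == 0:
            return
        probs = edge_probabilities(g)
        sub = sample_subgraph(g, probs, m=3, seed=seed)
        a_sub = _subgraph_adjacency(g, sub.nodes, sub.induced_edges, None)
        h = rng.normal(size=(n, 3))
        w = rng.normal(size=(3, 2))
        got = gcn_layer(h[sub.nodes], a_sub, w, "identity")
        local = {int(v): i for i, v in enumerate(sub.nodes)}
        loc_edges = [[local[int(u)], local[int(v)]] for u, v in sub.induced_edges]
        want = dense_oracle(len(sub.nodes), loc_edges, h[sub.nodes], w)
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestSmoothing:
    def test_cycle_variance_shrinks_towards_constant(self, graph_factory):
        """Convolution with W=I on a regular graph is Laplacian smoothing."""
        cycle = graph_factory(6, [[i, (i + 1) % 6] for i in range(6)])
        a = normalized_adjacency(cycle)
        h = np.random.default_rng(0).normal(size=(6, 1))
        var = [h.var()]
        for _ in range(30):
            h = gcn_layer(h, a, np.eye(1), "identity")
            var.append(h.var())
        assert all(b < a_ for a_, b in zip(var, var[1:]))
        assert var[-1] < 1e-6  # embeddings approach the constant vector


def planted_nodes(node_factory, n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    x = rng.normal(0, 0.3, size=(n, 4)) + y[:, None]
    roles = ["train" if i % 4 else "test-masked" for i in range(n)]
    return node_factory(x, labels=y, roles=roles)


@pytest.fixture
def small_config():
    return GCNConfig(hidden=(8, 4), epochs=15, batches_per_epoch=4, seed=0)


class TestTraining:
    def test_loss_decreases_and_history_deterministic(self, node_factory, small_config):
        from mdgcn.pair_graph import knn_regular_graph

        nodes = planted_nodes(node_factory)
        g = knn_regular_graph(nodes, k=4)
        probs = edge_probabilities(g)
        coeffs = estimate_normalization(g, probs, m=10, n_subgraphs=20, seed=1)
        m1 = train(small_config, g, nodes, sampler=(probs, coeffs), seed=3)
        m2 = train(small_config, g, nodes, sampler=(probs, coeffs), seed=3)
        assert m1.loss_history == m2.loss_history  # bitwise determinism
        assert m1.loss_history[-1] < m1.loss_history[0]

    def test_zero_learning_rate_freezes_loss(self, node_factory, small_config):
        from mdgcn.pair_graph import knn_regular_graph

        nodes = planted_nodes(node_factory)
        g = knn_regular_graph(nodes, k=4)
        cfg = GCNConfig(hidden=(8,), epochs=5, learning_rate=0.0, seed=0)
        model = train(cfg, g, nodes, seed=0)
        assert len(set(model.loss_history)) == 1

    def test_single_class_rejected(self, node_factory, graph_factory):
        nodes = planted_nodes(node_factory)
        nodes.table["label"] = 1
        g = graph_factory(len(nodes), [[i, i + 1] for i in range(len(nodes) - 1)])
        with pytest.raises(InputError, match="both classes"):
            train(GCNConfig(hidden=(4,), epochs=1), g, nodes)

    def test_checkpoint_round_trip(self, node_factory, small_config, tmp_path):
        from mdgcn.pair_graph import knn_regular_graph

        nodes = planted_nodes(node_factory)
        g = knn_regular_graph(nodes, k=4)
        model = train(small_config, g, nodes, seed=2)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedModel.load(path)
        for a, b in zip(model.conv_weights, loaded.conv_weights):
            assert np.array_equal(a, b)
        assert np.array_equal(model.out_weight, loaded.out_weight)
        assert model.out_bias == loaded.out_bias
        assert loaded.config == model.config
        np.testing.assert_array_equal(
            predict_scores(model, g, nodes), predict_scores(loaded, g, nodes)
        )


class TestPrediction:
    def test_scores_in_unit_interval_and_subset_consistent(
        self, node_factory, small_config
    ):
        from mdgcn.pair_graph import knn_regular_graph

        nodes = planted_nodes(node_factory)
        g = knn_regular_graph(nodes, k=4)
        model = train(small_config, g, nodes, seed=1)
        scores = predict_scores(model, g, nodes)
        assert ((scores >= 0) & (scores <= 1)).all()
        subset = np.array([3, 17, 40])
        np.testing.assert_array_equal(
            predict_scores(model, g, nodes, subset), scores[subset]
        )

    def test_zero_head_gives_half(self, node_factory, graph_factory):
        nodes = planted_nodes(node_factory, n=10)
        g = graph_factory(10, [[i, i + 1] for i in range(9)])
        model = TrainedModel(
            conv_weights=[np.zeros((4, 3))],
            out_weight=np.zeros((3, 1)),
            out_bias=0.0,
            config=GCNConfig(hidden=(3,)),
            input_dim=4,
        )
        assert (predict_scores(model, g, nodes) == 0.5).all()

    def test_unknown_node_id_rejected(self, node_factory, graph_factory):
        nodes = planted_nodes(node_factory, n=10)
        g = graph_factory(10, [[i, i + 1] for i in range(9)])
        model = TrainedModel(
            conv_weights=[np.zeros((4, 3))], out_weight=np.zeros((3, 1)),
            out_bias=0.0, config=GCNConfig(hidden=(3,)), input_dim=4,
        )
        with pytest.raises(InputError):
            predict_scores(model, g, nodes, [99])

    def test_permutation_equivariance(self, node_factory, graph_factory):
        """Relabeling nodes permutes predictions identically."""
        rng = np.random.default_rng(8)
        n = 12
        x = rng.normal(size=(n, 4))
        edges = [[i, (i + 3) % n] for i in range(n)]
        model = TrainedModel(
            conv_weights=[rng.normal(size=(4, 3))],
            out_weight=rng.normal(size=(3, 1)),
            out_bias=0.1,
            config=GCNConfig(hidden=(3,)),
            input_dim=4,
        )
        g = graph_factory(n, edges)
        base = predict_scores(model, g, node_factory(x))
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        g2 = graph_factory(n, [[perm[u], perm[v]] for u, v in edges])
        permuted = predict_scores(model, g2, node_factory(x[inv]))
        np.testing.assert_allclose(permuted[perm], base, atol=1e-12)
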
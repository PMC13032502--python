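"""GCN/GAT layers, attention fusion and the MLP head against dense oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

from lncgraph import autodiff as ad
from lncgraph.autodiff import Tensor
from lncgraph.config import ModelConfig
from lncgraph.model import GraphTensor, PairModel, gat_layer, gcn_layer
from lncgraph.pairs import PairGraph, make_pair_nodes


def graph_from_adjacency(adj: np.ndarray) -> GraphTensor:
    n = adj.shape[0]
    pairs = [(f"L{i}", f"D{i}") for i in range(n)]
    nodes = make_pair_nodes(pairs, [])
    return GraphTensor.from_graph(
        PairGraph(nodes, sp.csr_matrix(adj.astype(float)), kind="CG")
    )


def random_graph(rng, n, p=0.4):
    adj = (rng.random((n, n)) < p).astype(float)
    adj = np.maximum(adj, adj.T)
    np.fill_diagonal(adj, 0.0)
    return adj


class TestGcnLayer:
    def test_edgeless_identity(self):
        """No edges, identity weights, linear activation: output = input."""
        g = graph_from_adjacency(np.zeros((3, 3)))
        H = Tensor(np.arange(12, dtype=float).reshape(3, 4))
        out = gcn_layer(H, g, Tensor(np.eye(4)), activation=lambda x: x)
        np.testing.assert_allclose(out.value, H.value)

    def test_two_node_complete_graph_normalization(self):
        g = graph_from_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(g.norm_adjacency.toarray(), 0.5)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            adj = random_graph(rng, n)
            g = graph_from_adjacency(adj)
            H = rng.normal(size=(n, 5))
            W = rng.normal(size=(5, 3))
            got = gcn_layer(Tensor(H), g, Tensor(W)).value
            a_hat = adj + np.eye(n)
            d = np.diag(1.0 / np.sqrt(a_hat.sum(axis=1)))
            want = np.maximum(d @ a_hat @ d @ H @ W, 0.0)
            assert np.abs(got - want).max() <= 1e-6


def gat_oracle(adj, H, W, a_src, a_dst):
    """Dense per-node attention softmax over the self-inclusive neighborhood."""
    n = H.shape[0]
    Hw = H @ W
    out = np.zeros_like(Hw)
    alpha_full = np.zeros((n, n))
    for i in range(n):
        neigh = [j for j in range(n) if adj[i, j] or j == i]
        logits = []
        for j in neigh:
            z = float(Hw[j] @ a_src.ravel() + Hw[i] @ a_dst.ravel())
            logits.append(z if z > 0 else 0.2 * z)
        e = np.exp(np.array(logits) - max(logits))
        alpha = e / e.sum()
        for a, j in zip(alpha, neigh):
            alpha_full[i, j] = a
            out[i] += a * Hw[j]
    elu = np.where(out > 0, out, np.exp(np.minimum(out, 0)) - 1)
    return elu, alpha_full


class TestGatLayer:
    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(3, 11))
            adj = random_graph(rng, n)
            g = graph_from_adjacency(adj)
            H, W = rng.normal(size=(n, 4)), rng.normal(size=(4, 3))
            a_s, a_d = rng.normal(size=(3, 1)), rng.normal(size=(3, 1))
            out, alpha = gat_layer(Tensor(H), g, Tensor(W), Tensor(a_s), Tensor(a_d))
            want, alpha_want = gat_oracle(adj, H, W, a_s, a_d)
            assert np.abs(out.value - want).max() <= 1e-6
            src, dst = g.edges
            for e in range(len(src)):
                assert alpha.value[e, 0] == pytest.approx(alpha_want[dst[e], src[e]], abs=1e-8)

    def test_identical_features_give_uniform_attention(self):
        adj = random_graph(np.random.default_rng(2), 6)
        g = graph_from_adjacency(adj)
        H = np.ones((6, 4))
        rng = np.random.default_rng(3)
        _, alpha = gat_layer(
            Tensor(H), g, Tensor(rng.normal(size=(4, 3))),
            Tensor(rng.normal(size=(3, 1))), Tensor(rng.normal(size=(3, 1))),
        )
        src, dst = g.edges
        sizes = np.bincount(dst, minlength=6)
        np.testing.assert_allclose(alpha.value.ravel(), 1.0 / sizes[dst], atol=1e-12)

    def test_attention_sums_to_one_per_node(self):
        rng = np.random.default_rng(4)
        adj = random_graph(rng, 8)
        g = graph_from_adjacency(adj)
        _, alpha = gat_layer(
            Tensor(rng.normal(size=(8, 5))), g, Tensor(rng.normal(size=(5, 4))),
            Tensor(rng.normal(size=(4, 1))), Tensor(rng.normal(size=(4, 1))),
        )
        sums = np.zeros(8)
        np.add.at(sums, g.edges[1], alpha.value.ravel())
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)


def small_setup(seed=0, n=6, in_dim=4, variant="full"):
    rng = np.random.default_rng(seed)
    cfg = ModelConfig(gcn1_dim=5, gat_dim=4, gcn3_dim=3, attention_dim=3,
                      mlp_hidden=[4], dropout=0.0)
    cg = graph_from_adjacency(random_graph(rng, n))
    rfg = graph_from_adjacency(random_graph(rng, n))
    X = rng.normal(size=(n, in_dim))
    model = PairModel(in_dim, cfg, variant, seed=seed)
    return model, X, cg, rfg


class TestFusion:
    def test_identical_views_split_evenly(self):
        model, X, cg, _ = small_setup()
        H = Tensor(np.random.default_rng(5).normal(size=(6, model.K)))
        _, alphas = model.attention_fuse(H, H)
        np.testing.assert_allclose(alphas, 0.5, atol=1e-12)

    def test_log3_score_gap_gives_three_quarters(self):
        """w_CG - w_RFG = ln 3 per node => alpha_CG = 0.75 exactly."""
        cfg = ModelConfig(gcn1_dim=2, gat_dim=2, gcn3_dim=2, attention_dim=1,
                          mlp_hidden=[2], dropout=0.0)
        model = PairModel(3, cfg, "full", seed=0)
        K = model.K
        model.params["fuse.W"].value = np.eye(1, K)  # picks coordinate 0
        model.params["fuse.b"].value = np.zeros((1, 1))
        model.params["fuse.q"].value = np.ones((1, 1))
        x = 0.6
        y = x - np.log(3.0)
        H_cg = np.zeros((4, K)); H_cg[:, 0] = np.arctanh(x)
        H_rfg = np.zeros((4, K)); H_rfg[:, 0] = np.arctanh(y)
        _, alphas = model.attention_fuse(Tensor(H_cg), Tensor(H_rfg))
        np.testing.assert_allclose(alphas[:, 0], 0.75, atol=1e-10)

    def test_alphas_sum_to_one_after_training(self):
        model, X, cg, rfg = small_setup(seed=6)
        labels = np.array([1.0, 0, 1, 0, 1, 0])[:, None]
        opt = ad.Adam(model.parameters(), lr=1e-2)
        for _ in range(15):
            logits, alphas = model.forward(X, cg, rfg)
            np.testing.assert_allclose(alphas.sum(axis=1), 1.0, atol=1e-8)
            loss = ad.bce_with_logits(logits, labels)
            opt.zero_grad(); loss.backward(); opt.step()


class TestForward:
    def test_encode_view_dim_is_h1_plus_h3(self):
        model, X, cg, rfg = small_setup()
        F = model.encode_view("CG", Tensor(X), cg)
        assert F.value.shape == (6, 5 + 3)
        F2 = model.encode_view("RFG", Tensor(X), rfg)
        assert F2.value.shape == F.value.shape

    def test_zeroed_mlp_scores_half(self):
        model, X, cg, rfg = small_setup()
        for k, p in model.params.items():
            if k.startswith("mlp."):
                p.value = np.zeros_like(p.value)
        scores, _ = model.predict(X, cg, rfg)
        np.testing.assert_allclose(scores, 0.5)
        assert ((scores > 0) & (scores < 1)).all()

    def test_cg_only_ignores_rfg_perturbation(self):
        model, X, cg, rfg = small_setup(variant="cg")
        s1, _ = model.predict(X, cg, None)
        s2, _ = model.predict(X, cg, graph_from_adjacency(np.zeros((6, 6))))
        np.testing.assert_array_equal(s1, s2)

    def test_noatt_differs_from_full(self):
        full, X, cg, rfg = small_setup(variant="full")
        noatt, *_ = small_setup(variant="noatt")
        s_full, _ = full.predict(X, cg, rfg)
        s_noatt, _ = noatt.predict(X, cg, rfg)
        assert not np.allclose(s_full, s_noatt)

    def test_full_alpha_report_covers_every_node(self):
        model, X, cg, rfg = small_setup()
        _, alphas = model.predict(X, cg, rfg)
        assert alphas.shape == (6, 2)

    def test_permutation_equivariance(self):
        model, X, cg, rfg = small_setup(seed=8)
        rng = np.random.default_rng(9)
        perm = rng.permutation(6)

        def permute_graph(g: GraphTensor) -> GraphTensor:
            adj = np.zeros((6, 6))
            src, dst = g.edges
            for s, d in zip(src, dst):
                if s != d:
                    adj[perm[s], perm[d]] = 1
            return graph_from_adjacency(adj)

        s1, _ = model.predict(X, cg, rfg)
        Xp = np.empty_like(X)
        Xp[perm] = X
        sperm, _ = model.predict(Xp, permute_graph(cg), permute_graph(rfg))
        np.testing.assert_allclose(sperm[perm], s1, atol=1e-10)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Central finite differences on a 5-node forward + BCE loss."""
        rng = np.random.default_rng(10)
        cfg = ModelConfig(gcn1_dim=3, gat_dim=3, gcn3_dim=2, attention_dim=2,
                          mlp_hidden=[3], dropout=0.0)
        adj1, adj2 = random_graph(rng, 5), random_graph(rng, 5)
        cg, rfg = graph_from_adjacency(adj1), graph_from_adjacency(adj2)
        X = rng.normal(size=(5, 4))
        y = np.array([1.0, 0, 1, 0, 1])[:, None]
        model = PairModel(4, cfg, "full", seed=11)

        def loss_value():
            logits, _ = model.forward(X, cg, rfg)
            return float(ad.bce_with_logits(logits, y).value)

        logits, _ = model.forward(X, cg, rfg)
        loss = ad.bce_with_logits(logits, y)
        for p in model.parameters():
            p.grad = None
        loss.backward()
        eps = 1e-6
        for name in sorted(model.params):
            p = model.params[name]
            grad = p.grad if p.grad is not None else np.zeros_like(p.value)
            flat = p.value.ravel()
            idxs = range(flat.size) if flat.size <= 6 else \
                np.random.default_rng(12).choice(flat.size, 6, replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_value()
                flat[i] = orig - eps
                down = loss_value()
                flat[i] = orig
                fd = (up - down) / (2 * eps)
                scale = max(abs(fd), abs(grad.ravel()[i]), 1e-8)
                assert abs(fd - grad.ravel()[i]) / scale <= 1e-4, name
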
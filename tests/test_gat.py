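"""Graph attention fine-tuning: coefficients, forward pass, pipelines."""

from collections import OrderedDict
from dataclasses import replace

import numpy as np
import pytest

from fedmdl import nn
from fedmdl.federated import ParamVector
from fedmdl.gat import (DomainGraph, GATConfig, GATParams, attention_coeffs,
                        build_domain_graph, finetune_phi, flatten_head,
                        gat_forward, gcn_variant, unflatten_head)
from fedmdl.multidomain import build_model


def _head(rng, F=4, C=2):
    return ParamVector(OrderedDict([("W", rng.normal(size=(F, C))),
                                    ("b", rng.normal(size=C))]))


def oracle_attention(V, W, a, config):
    """Two-loop softmax reference for one head's attention row."""
    K = len(V)
    H = V @ W
    scores = np.zeros((K, K))
    for d in range(K):
        for j in range(K):
            if config.similarity == "concat-linear":
                s = a @ np.concatenate([H[d], H[j]])
            else:
                u = a * H[d]
                s = (u @ H[j]) / (np.linalg.norm(u) * np.linalg.norm(H[j]))
                s /= config.cosine_temperature
            scores[d, j] = s if s > 0 else config.leaky_relu_slope * s
    e = np.zeros((K, K))
    for d in range(K):
        nbr = [j for j in range(K) if j != d]
        ex = np.exp(scores[d, nbr] - scores[d, nbr].max())
        e[d, nbr] = ex / ex.sum()
    return e


def oracle_gat_layer(V, Ws, As, config):
    """Triple-loop reference for one multi-head-averaged layer."""
    K, M = V.shape
    out = np.zeros((K, M))
    for head in range(len(Ws)):
        e = oracle_attention(V, Ws[head], As[head], config)
        for d in range(K):
            for j in range(K):
                if j != d:
                    out[d] += e[d, j] * (V[j] @ Ws[head])
    out /= len(Ws)
    return np.where(out > 0, out, np.exp(out) - 1.0)  # ELU


class TestDomainGraph:
    def test_shapes_and_flatten_roundtrip(self):
        rng = np.random.default_rng(0)
        phi = {d: _head(rng) for d in (1, 2, 3)}
        g = build_domain_graph(phi, 4, 2)
        assert g.K == 3 and g.M == 4 * 2 + 2
        for d in (1, 2, 3):
            back = unflatten_head(flatten_head(phi[d]), 4, 2)
            np.testing.assert_array_equal(back["W"], phi[d]["W"])
            np.testing.assert_array_equal(back["b"], phi[d]["b"])

    def test_identical_heads_identical_vertices(self):
        rng = np.random.default_rng(1)
        h = _head(rng)
        g = build_domain_graph({1: h, 2: h.copy()}, 4, 2)
        np.testing.assert_array_equal(g.vertices[0], g.vertices[1])

    def test_k1_errors(self):
        with pytest.raises(ValueError):
            build_domain_graph({1: _head(np.random.default_rng(0))}, 4, 2)


class TestAttentionCoeffs:
    @pytest.mark.parametrize("similarity", ["scaled-cosine", "concat-linear"])
    def test_rows_sum_to_one_with_zero_diagonal(self, similarity):
        rng = np.random.default_rng(0)
        cfg = GATConfig(similarity=similarity)
        for _ in range(10):
            K, M = rng.integers(2, 6), rng.integers(2, 8)
            V = rng.normal(size=(K, M))
            W = nn.Tensor(rng.normal(size=(M, M)))
            a_dim = 2 * M if similarity == "concat-linear" else M
            a = nn.Tensor(rng.normal(size=a_dim))
            e = attention_coeffs(V, W, a, cfg).data
            np.testing.assert_allclose(e.sum(axis=1), 1.0, atol=1e-6)
            np.testing.assert_allclose(np.diag(e), 0.0, atol=1e-12)
            assert np.all(e >= 0)

    def test_identical_vertices_give_uniform_attention(self):
        rng = np.random.default_rng(1)
        cfg = GATConfig()
        V = np.tile(rng.normal(size=4), (5, 1))
        W = nn.Tensor(rng.normal(size=(4, 4)))
        a = nn.Tensor(rng.normal(size=4))
        e = attention_coeffs(V, W, a, cfg).data
        off = e[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.25, atol=1e-12)

    @pytest.mark.parametrize("similarity", ["scaled-cosine", "concat-linear"])
    def test_matches_two_loop_oracle(self, similarity):
        rng = np.random.default_rng(2)
        cfg = GATConfig(similarity=similarity, cosine_temperature=1.0)
        V = rng.normal(size=(3, 2))
        W = rng.normal(size=(2, 2))
        a = rng.normal(size=4 if similarity == "concat-linear" else 2)
        ours = attention_coeffs(V, nn.Tensor(W), nn.Tensor(a), cfg).data
        np.testing.assert_allclose(ours, oracle_attention(V, W, a, cfg),
                                   atol=1e-7)

    def test_zero_norm_vertex_errors_without_guard(self):
        cfg = GATConfig(similarity="scaled-cosine")
        V = np.zeros((3, 4))
        W = nn.Tensor(np.eye(4))
        a = nn.Tensor(np.ones(4))
        with pytest.raises(ValueError, match="cosine_eps"):
            attention_coeffs(V, W, a, cfg)
        guarded = replace(cfg, cosine_eps=1e-8)
        e = attention_coeffs(V, W, a, guarded).data
        np.testing.assert_allclose(e.sum(axis=1), 1.0, atol=1e-6)

    def test_uniform_mode_constant_weights(self):
        cfg = GATConfig(similarity="uniform")
        rng = np.random.default_rng(3)
        for _ in range(3):
            V = rng.normal(size=(4, 3))
            e = attention_coeffs(V, nn.Tensor(np.eye(3)), None, cfg).data
            np.testing.assert_allclose(e[~np.eye(4, dtype=bool)], 1 / 3)


class TestGatForward:
    def _graph(self, rng, K=4, M=3):
        return DomainGraph(vertices=rng.normal(size=(K, M)),
                           feature_dim=1, n_classes=1)

    def test_one_layer_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        for L in (1, 2, 3):
            cfg = GATConfig(n_layers=1, n_heads=L, dropout=0.0,
                            cosine_temperature=1.0)
            g = self._graph(rng)
            params = GATParams(g.M, cfg, seed=0)
            ours = gat_forward(g, params, cfg, training=False).data
            Ws = [params.W[0][h].data for h in range(L)]
            As = [params.a[0][h].data for h in range(L)]
            ref = oracle_gat_layer(g.vertices, Ws, As, cfg)
            np.testing.assert_allclose(ours, ref, atol=1e-6)

    def test_k2_forced_attention(self):
        # with a single neighbor the attention weight is exactly 1, so
        # each output row is ELU of the neighbor's projection
        rng = np.random.default_rng(5)
        cfg = GATConfig(n_layers=1, n_heads=1, dropout=0.0)
        g = DomainGraph(vertices=rng.normal(size=(2, 4)), feature_dim=1,
                        n_classes=2)
        params = GATParams(4, cfg, seed=1)
        out = gat_forward(g, params, cfg, training=False).data
        W = params.W[0][0].data
        expect = np.stack([g.vertices[1] @ W, g.vertices[0] @ W])
        expect = np.where(expect > 0, expect, np.exp(expect) - 1)
        np.testing.assert_allclose(out, expect, atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        cfg = GATConfig(n_layers=2, n_heads=2, dropout=0.0)
        g = self._graph(rng, K=5, M=4)
        params = GATParams(4, cfg, seed=2)
        out = gat_forward(g, params, cfg, training=False).data
        perm = rng.permutation(5)
        g2 = DomainGraph(vertices=g.vertices[perm], feature_dim=1, n_classes=1)
        out2 = gat_forward(g2, params, cfg, training=False).data
        np.testing.assert_allclose(out2, out[perm], atol=1e-10)

    def test_eval_mode_deterministic_despite_dropout_config(self):
        rng = np.random.default_rng(7)
        cfg = GATConfig(n_layers=2, n_heads=2, dropout=0.5)
        g = self._graph(rng)
        params = GATParams(g.M, cfg, seed=3)
        o1 = gat_forward(g, params, cfg, training=False).data
        o2 = gat_forward(g, params, cfg, training=False).data
        np.testing.assert_array_equal(o1, o2)

    def test_k2_gcn_equals_gat_with_matched_weights(self):
        rng = np.random.default_rng(8)
        gat_cfg = GATConfig(n_layers=1, n_heads=2, dropout=0.0)
        gcn_cfg = replace(gat_cfg, similarity="uniform")
        g = DomainGraph(vertices=rng.normal(size=(2, 3)), feature_dim=1,
                        n_classes=1)
        params = GATParams(3, gat_cfg, seed=4)
        out_gat = gat_forward(g, params, gat_cfg, training=False).data
        out_gcn = gat_forward(g, params, gcn_cfg, training=False).data
        np.testing.assert_allclose(out_gat, out_gcn, atol=1e-12)


class TestFinetunePipelines:
    def _setup(self):
        from fedmdl.synthetic import SyntheticConfig, generate_federation
        from fedmdl.clustergan import DomainAssignment
        fed = generate_federation(SyntheticConfig(
            n_clients=2, n_domains_true=2, samples_per_client=50,
            conflicting_labels=True, noise_sd=0.05, seed=6))
        model = build_model("desk", 2, 2, seed=0)
        labels = OrderedDict((str(c.client_id), c.true_domains)
                             for c in fed.clients)
        asg = DomainAssignment(labels=labels, centroids=np.zeros((2, 4)), K=2)
        return model, fed.clients, asg

    def test_epochs_zero_residual_returns_near_initial_heads(self):
        model, clients, asg = self._setup()
        cfg = GATConfig(epochs=0, cosine_eps=1e-8)
        phi2 = finetune_phi(model, clients, asg, cfg)
        # residual form: phi' = phi + GAT(phi); untrained output is bounded
        for d in (1, 2):
            delta = np.linalg.norm(flatten_head(phi2[d])
                                   - flatten_head(model.phi[d]))
            assert np.isfinite(delta)

    def test_single_client_no_aggregation(self):
        model, clients, asg = self._setup()
        cfg = GATConfig(epochs=1, cosine_eps=1e-8, seed=0)
        solo = finetune_phi(model, clients[:1], asg, cfg)
        assert set(solo) == {1, 2}

    def test_k1_skips_with_original_heads(self):
        model = build_model("desk", 1, 2, seed=0)
        cfg = GATConfig(epochs=1)
        out = finetune_phi(model, [], None, cfg)
        np.testing.assert_array_equal(out[1]["W"], model.phi[1]["W"])

    def test_gcn_variant_runs_same_pipeline(self):
        model, clients, asg = self._setup()
        cfg = GATConfig(epochs=1, cosine_eps=1e-8, seed=0)
        out = gcn_variant(model, clients, asg, cfg)
        assert set(out) == {1, 2}
        for d in (1, 2):
            assert out[d]["W"].shape == model.phi[d]["W"].shape

    def test_finetune_deterministic_under_seed(self):
        model, clients, asg = self._setup()
        cfg = GATConfig(epochs=1, cosine_eps=1e-8, seed=5)
        p1 = finetune_phi(model, clients, asg, cfg)
        p2 = finetune_phi(model, clients, asg, cfg)
        for d in (1, 2):
            np.testing.assert_array_equal(p1[d]["W"], p2[d]["W"])
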
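"""Multi-domain classifier: routing, frozen backbone, per-head aggregation."""

from collections import OrderedDict

import numpy as np
import pytest

from fedmdl.clustergan import DomainAssignment
from fedmdl.federated import ParamVector, TrainConfig
from fedmdl.multidomain import (build_model, federated_train_multidomain,
                                forward_routed, infer, local_train_multidomain)
from fedmdl.synthetic import ClientDataset, SyntheticConfig, generate_federation


def _set_head(model, d, W, b):
    model.phi[d] = ParamVector(OrderedDict([("W", W), ("b", b)]))


class TestBuildModel:
    def test_shapes_and_determinism(self):
        m1 = build_model("desk", 3, 2, seed=7)
        m2 = build_model("desk", 3, 2, seed=7)
        for d in (1, 2, 3):
            assert m1.phi[d]["W"].shape == (m1.feature_dim, 2)
            assert m1.phi[d]["b"].shape == (2,)
            np.testing.assert_array_equal(m1.phi[d]["W"], m2.phi[d]["W"])
        # heads are independent draws
        assert not np.array_equal(m1.phi[1]["W"], m1.phi[2]["W"])

    def test_k1_reduces_to_single_head(self):
        m = build_model("desk", 1, 2, seed=0)
        assert list(m.phi) == [1]

    def test_unknown_spec_errors(self):
        with pytest.raises(ValueError):
            build_model("mystery", 2, 2, seed=0)
        with pytest.raises(RuntimeError):
            build_model("resnet50", 2, 2, seed=0)

    def test_theta_marked_frozen(self):
        m = build_model("desk", 2, 2, seed=0)
        assert not any(m.theta.trainable_mask.values())


class TestForwardRouted:
    def test_constant_heads_follow_routing(self):
        m = build_model("desk", 2, 2, seed=0)
        _set_head(m, 1, np.zeros((m.feature_dim, 2)), np.array([10.0, 0.0]))
        _set_head(m, 2, np.zeros((m.feature_dim, 2)), np.array([0.0, 10.0]))
        imgs = np.random.default_rng(0).random((6, 16, 16))
        doms = np.array([1, 2, 1, 2, 1, 2])
        pred = forward_routed(m, imgs, doms).argmax(axis=1)
        np.testing.assert_array_equal(pred, doms - 1)

    def test_single_domain_equals_single_head_forward(self):
        m = build_model("desk", 3, 2, seed=1)
        imgs = np.random.default_rng(1).random((5, 16, 16))
        routed = forward_routed(m, imgs, np.full(5, 2))
        f = m.features(imgs)
        direct = f @ m.phi[2]["W"] + m.phi[2]["b"]
        np.testing.assert_allclose(routed, direct, atol=1e-12)

    def test_identical_image_different_domain_different_logits(self):
        m = build_model("desk", 2, 2, seed=2)
        img = np.random.default_rng(2).random((1, 16, 16))
        both = np.concatenate([img, img])
        out = forward_routed(m, both, np.array([1, 2]))
        assert not np.allclose(out[0], out[1])

    def test_out_of_range_domain_errors(self):
        m = build_model("desk", 2, 2, seed=0)
        with pytest.raises(ValueError):
            forward_routed(m, np.zeros((1, 16, 16)), np.array([3]))


class TestLocalTraining:
    def _client(self, seed=0):
        fed = generate_federation(SyntheticConfig(
            n_clients=1, n_domains_true=2, samples_per_client=80,
            conflicting_labels=True, noise_sd=0.05, seed=seed))
        return fed.clients[0]

    def test_theta_bit_identical_and_absent_heads_untouched(self):
        c = self._client()
        m = build_model("desk", 3, 2, seed=0)
        theta_before = {k: m.theta[k].copy() for k in m.theta.names()}
        phi3_before = m.phi[3]["W"].copy()
        doms = c.true_domains  # only domains 1 and 2 occur
        local_train_multidomain(m, c, doms, epochs=3, lr=0.03,
                                rng=np.random.default_rng(0))
        for k, v in theta_before.items():
            np.testing.assert_array_equal(m.theta[k], v)
        np.testing.assert_array_equal(m.phi[3]["W"], phi3_before)
        assert not np.array_equal(m.phi[1]["W"], build_model(
            "desk", 3, 2, seed=0).phi[1]["W"])

    def test_separable_data_fits(self):
        c = self._client(seed=3)
        m = build_model("desk", 2, 2, seed=0)
        local_train_multidomain(m, c, c.true_domains, epochs=20, lr=0.03,
                                rng=np.random.default_rng(0))
        acc = np.mean(forward_routed(m, c.images, c.true_domains).argmax(1)
                      == c.class_labels)
        assert acc >= 0.95

    def test_mismatched_domain_labels_error(self):
        c = self._client()
        m = build_model("desk", 2, 2, seed=0)
        with pytest.raises(ValueError):
            local_train_multidomain(m, c, np.array([1, 2]), epochs=1)


def _assignment_from_truth(clients, K):
    labels = OrderedDict((str(c.client_id), c.true_domains) for c in clients)
    return DomainAssignment(labels=labels,
                            centroids=np.zeros((K, 4)), K=K)


class TestFederatedTraining:
    def _clients(self, n=2, seed=0):
        fed = generate_federation(SyntheticConfig(
            n_clients=n, n_domains_true=2, samples_per_client=60,
            conflicting_labels=True, noise_sd=0.05, seed=seed))
        return fed.clients

    def test_frozen_theta_hash_conserved(self):
        clients = self._clients()
        asg = _assignment_from_truth(clients, 2)
        cfg = TrainConfig(learning_rate=0.03, batch_size=32, max_rounds=3,
                          early_stop_patience=3, seed=0)
        init = build_model("desk", 2, 2, seed=0)
        h = init.theta_hash()
        out = federated_train_multidomain(clients, asg, cfg, model=init)
        assert out.theta_hash() == h

    def test_exclusive_domain_head_comes_from_owning_client(self):
        # client B holds only domain 1; global phi_2 must equal A's phi_2
        clients = self._clients(2, seed=1)
        a, b = clients
        b = ClientDataset(images=b.images[b.true_domains == 1],
                          class_labels=b.class_labels[b.true_domains == 1],
                          true_domains=b.true_domains[b.true_domains == 1],
                          client_id=b.client_id)
        asg = _assignment_from_truth([a, b], 2)
        cfg = TrainConfig(learning_rate=0.03, batch_size=32, max_rounds=1,
                          early_stop_patience=1, seed=0)
        init = build_model("desk", 2, 2, seed=0)
        out = federated_train_multidomain([a, b], asg, cfg,
                                          model=init, val_fraction=0.0)
        solo = federated_train_multidomain([a], _assignment_from_truth([a], 2),
                                           cfg, model=init, val_fraction=0.0)
        np.testing.assert_allclose(out.phi[2]["W"], solo.phi[2]["W"], atol=1e-10)

    def test_symmetric_clients_aggregate_to_single_client_heads(self):
        # identical data + identical local rng: the per-head weighted mean
        # of the two local updates equals either one
        from fedmdl.multidomain import _aggregate_heads
        a = self._clients(1, seed=2)[0]
        init = build_model("desk", 2, 2, seed=0)
        locals_ = []
        for _ in range(2):
            local = init.copy()
            local_train_multidomain(local, a, a.true_domains, epochs=2,
                                    lr=0.03, rng=np.random.default_rng(5))
            locals_.append(local)
        counts = {int(d): int(np.sum(a.true_domains == d))
                  for d in np.unique(a.true_domains)}
        merged = _aggregate_heads(locals_, [counts, counts], init)
        for d in (1, 2):
            np.testing.assert_allclose(merged.phi[d]["W"],
                                       locals_[0].phi[d]["W"], atol=1e-12)


class TestInfer:
    def test_training_image_gets_training_domain(self, trained_gan,
                                                 trained_assignment,
                                                 three_domain_federation):
        c = three_domain_federation.clients[0]
        model = build_model("desk", 3, 2, seed=0)
        from fedmdl.clustergan import encode
        codes = encode(trained_gan, c.images[:10])
        again = trained_assignment.assign_new(codes)
        np.testing.assert_array_equal(
            again, trained_assignment.assign_new(codes))

    def test_nearest_centroid_picks_closer(self):
        asg = DomainAssignment(labels=OrderedDict(),
                               centroids=np.array([[0.0, 0.0], [100.0, 100.0]]),
                               K=2)
        codes = np.array([[1.0, 1.0], [99.0, 99.0]])
        np.testing.assert_array_equal(asg.assign_new(codes), [1, 2])

    def test_missing_centroids_error(self):
        model = build_model("desk", 2, 2, seed=0)
        asg = DomainAssignment(labels=OrderedDict(),
                               centroids=np.zeros((0, 2)), K=2)
        with pytest.raises(ValueError):
            infer(model, np.zeros((1, 16, 16)), asg, encoder=None)
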
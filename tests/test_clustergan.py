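"""ClusterGAN: latent prior, objective values, training, domain assignment."""

from collections import OrderedDict

import numpy as np
import pytest

from fedmdl import nn
from fedmdl.clustergan import (ClusterGANModel, LatentPrior, LossConfig,
                               assign_domains, clustergan_losses, encode,
                               local_train_clustergan, sample_latent)
from fedmdl.domain_search import cluster_purity
from fedmdl.synthetic import ClientDataset


class TestSampleLatent:
    def test_one_hot_rows(self):
        rng = np.random.default_rng(0)
        _, z_c = sample_latent(50, LatentPrior(K=4), rng)
        assert np.all(z_c.sum(axis=1) == 1)
        assert np.all((z_c == 0) | (z_c == 1))

    def test_small_sigma_concentrates(self):
        rng = np.random.default_rng(0)
        z_n, _ = sample_latent(100, LatentPrior(K=2, sigma=1e-9), rng)
        assert np.max(np.abs(z_n)) < 1e-7

    def test_sample_std_within_chi_square_bound(self):
        rng = np.random.default_rng(1)
        z_n, _ = sample_latent(10000, LatentPrior(K=2, sigma=0.1, dim_zn=5), rng)
        stds = z_n.std(axis=0)
        assert np.all(stds > 0.095) and np.all(stds < 0.105)

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            LatentPrior(K=1)
        with pytest.raises(ValueError):
            LatentPrior(K=2, sigma=0.0)


class _StubModel:
    """Injectable G/D/E for hand-computable objective values."""

    def __init__(self, d_value, dim_zn, K, perfect_encoder=True):
        self.d_value = d_value
        self.prior = LatentPrior(K=K, dim_zn=dim_zn)
        self._latents = None
        self.perfect = perfect_encoder

    def generate(self, z):
        self._latents = z.data
        return nn.Tensor(np.zeros((len(z.data), 4)))

    def discriminate(self, x):
        return nn.Tensor(np.full((x.shape[0], 1), self.d_value))

    def encode_split(self, x):
        dzn = self.prior.dim_zn
        z_n = self._latents[:, :dzn]
        z_c = self._latents[:, dzn:]
        logits = np.where(z_c == 1, 1e4, -1e4)
        return nn.Tensor(z_n), nn.Tensor(logits)


class TestObjectiveValues:
    def test_log_mode_hand_value(self):
        # D == 0.5 and a perfect encoder: log 0.5 + log 0.5, regularizers 0
        model = _StubModel(0.5, dim_zn=3, K=2)
        rng = np.random.default_rng(0)
        z = sample_latent(8, model.prior, rng)
        out = clustergan_losses(np.zeros((8, 4)), z, model, LossConfig())
        assert out.objective == pytest.approx(2 * np.log(0.5), abs=1e-3)
        assert out.regularizer == pytest.approx(0.0, abs=1e-6)

    def test_wasserstein_constant_discriminator(self):
        rng = np.random.default_rng(0)
        for c in (-1.3, 0.0, 2.7):
            model = _StubModel(c, dim_zn=3, K=2)
            z = sample_latent(8, model.prior, rng)
            out = clustergan_losses(
                np.zeros((8, 4)), z, model,
                LossConfig(quality_mode="wasserstein", beta_n=0, beta_c=0))
            assert out.adversarial == pytest.approx(1.0, abs=1e-12)

    def test_beta_zero_reduces_to_adversarial(self):
        model = _StubModel(0.3, dim_zn=3, K=2, perfect_encoder=False)
        rng = np.random.default_rng(0)
        z = sample_latent(8, model.prior, rng)
        out = clustergan_losses(np.zeros((8, 4)), z, model,
                                LossConfig(beta_n=0, beta_c=0))
        assert out.objective == pytest.approx(out.adversarial, abs=1e-12)

    def test_log_mode_rejects_unsquashed_scores(self):
        model = _StubModel(1.5, dim_zn=3, K=2)
        rng = np.random.default_rng(0)
        z = sample_latent(4, model.prior, rng)
        with pytest.raises(ValueError):
            clustergan_losses(np.zeros((4, 4)), z, model, LossConfig())

    def test_perfect_encoder_zero_crossentropy_gradient(self):
        # with beta_c > 0 and E matching z_c exactly, the CE term's
        # gradient through the logits vanishes (softmax == one-hot)
        logits = np.where(np.eye(3) == 1, 1e4, -1e4)
        t = nn.Tensor(logits, requires_grad=True)
        loss = t.cross_entropy(np.arange(3))
        loss.backward()
        assert np.max(np.abs(t.grad)) < 1e-12


class TestLocalTraining:
    def _data(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        return ClientDataset(images=rng.random((n, 8, 8)),
                             class_labels=np.zeros(n, dtype=int), client_id="0")

    def test_zero_epochs_is_noop(self):
        model = ClusterGANModel(8, LatentPrior(K=2), seed=0)
        before = model.get_params()
        out = local_train_clustergan(model, self._data(), model.prior,
                                     LossConfig(), epochs=0)
        assert out.get_params().allclose(before)

    def test_fixed_seed_determinism(self):
        results = []
        for _ in range(2):
            model = ClusterGANModel(8, LatentPrior(K=2), seed=3)
            local_train_clustergan(model, self._data(), model.prior,
                                   LossConfig(), epochs=1,
                                   rng=np.random.default_rng(7))
            results.append(model.get_params())
        assert results[0].allclose(results[1])

    def test_empty_data_errors(self):
        model = ClusterGANModel(8, LatentPrior(K=2), seed=0)
        empty = ClientDataset(images=np.zeros((0, 8, 8)),
                              class_labels=np.zeros(0, dtype=int), client_id="0")
        with pytest.raises(ValueError):
            local_train_clustergan(model, empty, model.prior, LossConfig())

    def test_two_identical_clients_match_single_client(self):
        # identical data + identical local rng streams -> the average of
        # the two local updates equals either one, i.e. the single-client run
        data = self._data(seed=5)
        outs = []
        for _ in range(2):
            model = ClusterGANModel(8, LatentPrior(K=2), seed=1)
            local_train_clustergan(model, data, model.prior, LossConfig(),
                                   epochs=1, rng=np.random.default_rng(9))
            outs.append(model.get_params())
        from fedmdl.federated import aggregate
        merged = aggregate(outs, [1, 1])
        assert merged.allclose(outs[0], tol=1e-12)


class TestEncodeAndAssign:
    def test_encode_shape_and_determinism(self):
        model = ClusterGANModel(8, LatentPrior(K=3, dim_zn=7), seed=0)
        imgs = np.random.default_rng(0).random((5, 8, 8))
        codes = encode(model, imgs)
        assert codes.shape == (5, 7 + 3)
        np.testing.assert_array_equal(codes, encode(model, imgs))
        # categorical block is a probability vector
        np.testing.assert_allclose(codes[:, 7:].sum(axis=1), 1.0, atol=1e-9)

    def test_encode_shape_mismatch_errors(self):
        model = ClusterGANModel(8, LatentPrior(K=2), seed=0)
        with pytest.raises(ValueError):
            encode(model, np.zeros((3, 16, 16)))

    def test_point_mass_codes_assign_perfectly(self):
        # three distinct constant images repeated -> 3 latent point masses
        model = ClusterGANModel(8, LatentPrior(K=3), seed=0)
        base = np.stack([np.full((8, 8), v) for v in (0.0, 0.5, 1.0)])
        imgs = np.repeat(base, 10, axis=0)
        truth = np.repeat([1, 2, 3], 10)
        ds = ClientDataset(images=imgs, class_labels=np.zeros(30, dtype=int),
                           client_id="0", true_domains=truth)
        asg = assign_domains(model, [ds], K=3, seed=0)
        labels = asg.labels["0"]
        assert cluster_purity(labels, truth) == 1.0
        codes = encode(model, imgs)
        for d in (1, 2, 3):
            member = codes[labels == d]
            assert np.allclose(member.var(axis=0), 0.0, atol=1e-18)

    def test_assignment_seeded_determinism(self, trained_gan,
                                           three_domain_federation):
        a1 = assign_domains(trained_gan, three_domain_federation.clients, 3,
                            seed=4)
        a2 = assign_domains(trained_gan, three_domain_federation.clients, 3,
                            seed=4)
        for cid in a1.labels:
            np.testing.assert_array_equal(a1.labels[cid], a2.labels[cid])

    def test_high_snr_purity(self, trained_gan, three_domain_federation,
                             trained_assignment):
        assigned = np.concatenate([trained_assignment.labels[str(c.client_id)]
                                   for c in three_domain_federation.clients])
        truth = np.concatenate([c.true_domains
                                for c in three_domain_federation.clients])
        assert cluster_purity(assigned, truth) >= 0.9

    def test_degenerate_codes_error(self):
        model = ClusterGANModel(8, LatentPrior(K=3), seed=0)
        imgs = np.zeros((10, 8, 8))
        ds = ClientDataset(images=imgs, class_labels=np.zeros(10, dtype=int),
                           client_id="0")
        with pytest.raises(ValueError):
            assign_domains(model, [ds], K=3, seed=0)


def test_latent_clustering_at_least_as_pure_as_pixel_clustering(
        trained_gan, three_domain_federation, trained_assignment):
    from sklearn.cluster import KMeans
    clients = three_domain_federation.clients
    truth = np.concatenate([c.true_domains for c in clients])
    latent = np.concatenate([trained_assignment.labels[str(c.client_id)]
                             for c in clients])
    X = np.concatenate([c.images.reshape(len(c), -1) for c in clients])
    pixel = KMeans(n_clusters=3, n_init=10, random_state=11).fit(X).labels_ + 1
    assert cluster_purity(latent, truth) >= cluster_purity(pixel, truth)


def test_model_checkpoint_roundtrip(tmp_path):
    model = ClusterGANModel(8, LatentPrior(K=2, dim_zn=5, sigma=0.2), seed=2)
    model.save(tmp_path / "ckpt.npz")
    back = ClusterGANModel.load(tmp_path / "ckpt.npz")
    assert back.get_params().allclose(model.get_params())
    assert back.prior.dim_zn == 5 and back.prior.sigma == 0.2
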
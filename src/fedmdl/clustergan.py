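"""Federated ClusterGAN: latent-space domain discovery.

A ClusterGAN couples three networks — generator G (latent -> image),
discriminator D (image -> realness score), encoder E (image -> latent
estimate) — over a mixed latent prior z = (z_n, z_c): a continuous
Gaussian z_n ~ N(0, sigma^2 I) and a discrete one-hot z_c uniform over K
categories. The training objective is the adversarial value function
plus two inversion regularizers that force E to recover the latent code
that generated each fake image:

    min_{G,E} max_D  E_x q(D(x)) + E_z q(1 - D(G(z)))
               + beta_n E_z ||z_n - E_n(G(z))||^2
               + beta_c E_z CE(z_c, E_c(G(z)))

with q = log (vanilla GAN; D emits a probability in (0,1)) or q = x
(Wasserstein mode, no gradient penalty — experimental). Because E maps
like images to like latent codes, K-Means in the encoded latent space
yields more stable cluster (domain) assignments than clustering raw
pixels.

Training is federated: each client runs local alternating D / (G,E)
steps, and the server averages all three parameter sets each round.
Domains are then assigned by pooling every client's encoded codes and
running K-Means server-side, so the domain space is shared across
clients.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.cluster import KMeans

from . import nn
from .federated import ParamVector, TrainConfig, run_rounds
from .synthetic import ClientDataset

__all__ = [
    "LatentPrior",
    "LossConfig",
    "ClusterGANModel",
    "DomainAssignment",
    "ClusterGANLosses",
    "sample_latent",
    "clustergan_losses",
    "local_train_clustergan",
    "federated_train_clustergan",
    "encode",
    "assign_domains",
]


@dataclass
class LatentPrior:
    """Mixed continuous + categorical latent prior."""

    K: int
    dim_zn: int = 30
    sigma: float = 0.1

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.K < 2:
            raise ValueError("K must be >= 2")

    @property
    def dim(self) -> int:
        return self.dim_zn + self.K


@dataclass
class LossConfig:
    quality_mode: str = "log"        # "log" (vanilla GAN) | "wasserstein"
    beta_n: float = 10.0
    beta_c: float = 10.0

    def __post_init__(self):
        if self.quality_mode not in ("log", "wasserstein"):
            raise ValueError("quality_mode must be 'log' or 'wasserstein'")
        if self.beta_n < 0 or self.beta_c < 0:
            raise ValueError("regularization coefficients must be >= 0")


def sample_latent(n: int, prior: LatentPrior, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Draw n latent codes: Gaussian z_n and exact one-hot z_c."""
    if n < 1:
        raise ValueError("n must be >= 1")
    z_n = rng.normal(0.0, prior.sigma, size=(n, prior.dim_zn))
    cats = rng.integers(0, prior.K, size=n)
    z_c = np.zeros((n, prior.K))
    z_c[np.arange(n), cats] = 1.0
    return z_n, z_c


class ClusterGANModel:
    """G/D/E as size-parameterized MLPs over flattened images.

    In log mode the discriminator's final activation is a sigmoid, so
    its output is the squashed probability the adversarial log terms
    expect; in Wasserstein mode it is a raw linear score.
    """

    def __init__(self, image_size: int, prior: LatentPrior,
                 quality_mode: str = "log", hidden: int = 64, seed: int = 42):
        self.image_size = image_size
        self.prior = prior
        self.quality_mode = quality_mode
        p = image_size * image_size
        rng = np.random.default_rng(seed)
        self.G = nn.MLP(rng, [prior.dim, hidden, p], ["tanh", "sigmoid"], name="G")
        d_out = "sigmoid" if quality_mode == "log" else "linear"
        self.D = nn.MLP(rng, [p, hidden, 1], ["tanh", d_out], name="D")
        self.E = nn.MLP(rng, [p, hidden, prior.dim], ["tanh", "linear"], name="E")

    # -- forward pieces -----------------------------------------------------
    def generate(self, z: nn.Tensor) -> nn.Tensor:
        return self.G(z)

    def discriminate(self, x: nn.Tensor) -> nn.Tensor:
        return self.D(x)

    def encode_split(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        # split columns: first dim_zn continuous, rest categorical logits
        out = self.E(x)
        dzn = self.prior.dim_zn
        zn = nn.Tensor(out.data[:, :dzn], out.requires_grad, (out,))
        zc = nn.Tensor(out.data[:, dzn:], out.requires_grad, (out,))

        def _b_zn():
            if out.requires_grad:
                g = np.zeros_like(out.data)
                g[:, :dzn] = zn.grad
                out._accum(g)

        def _b_zc():
            if out.requires_grad:
                g = np.zeros_like(out.data)
                g[:, dzn:] = zc.grad
                out._accum(g)

        zn._backward = _b_zn
        zc._backward = _b_zc
        return zn, zc

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        return OrderedDict([("G", self.G), ("D", self.D), ("E", self.E)])

    def get_params(self) -> ParamVector:
        tensors: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for mod in self._modules().values():
            for name, t in mod.parameters().items():
                tensors[name] = t.data.copy()
        return ParamVector(tensors)

    def set_params(self, pv: ParamVector):
        for mod in self._modules().values():
            for name, t in mod.parameters().items():
                t.data = np.array(pv[name]).reshape(t.data.shape)

    def save(self, path):
        pv = self.get_params()
        pv.save(path)
        import json
        header = {"image_size": self.image_size, "quality_mode": self.quality_mode,
                  "prior": {"K": self.prior.K, "dim_zn": self.prior.dim_zn,
                            "sigma": self.prior.sigma}}
        Path(str(path) + ".model.json").write_text(json.dumps(header))

    @classmethod
    def load(cls, path) -> "ClusterGANModel":
        import json
        header = json.loads(Path(str(path) + ".model.json").read_text())
        prior = LatentPrior(**header["prior"])
        model = cls(header["image_size"], prior, header["quality_mode"])
        model.set_params(ParamVector.load(path))
        return model


class ClusterGANLosses(NamedTuple):
    d_loss: nn.Tensor        # discriminator descends this (= -adversarial value)
    ge_loss: nn.Tensor       # generator+encoder descend this
    adversarial: float       # E q(D(x)) + E q(1 - D(G(z)))
    regularizer: float       # beta_n * MSE + beta_c * CE
    objective: float         # adversarial + regularizer (the printed value)


def clustergan_losses(real_batch: np.ndarray,
                      fake_batch_latents: tuple[np.ndarray, np.ndarray],
                      model, loss_config: LossConfig) -> ClusterGANLosses:
    """Evaluate the ClusterGAN objective on one batch.

    Returns the two optimization targets (d_loss for D's ascent written
    as a descent, ge_loss for G/E) plus scalar diagnostics.
    """
    z_n, z_c = fake_batch_latents
    if len(real_batch) == 0 or len(z_n) == 0:
        raise ValueError("batches must be nonempty")
    x_r = nn.Tensor(np.asarray(real_batch).reshape(len(real_batch), -1))
    z = nn.Tensor(np.concatenate([z_n, z_c], axis=1))
    x_g = model.generate(z)
    s_r = model.discriminate(x_r)
    s_f = model.discriminate(x_g)

    if loss_config.quality_mode == "log":
        for s in (s_r, s_f):
            if np.any(s.data <= 0) or np.any(s.data >= 1):
                raise ValueError("log quality mode requires squashed scores in (0,1)")
        term_real = s_r.log().mean()
        term_fake = (1.0 - s_f).log().mean()
    else:
        term_real = s_r.mean()
        term_fake = (1.0 - s_f).mean()

    zn_hat, zc_logits = model.encode_split(x_g)
    diff = nn.Tensor(z_n) - zn_hat
    mse = (diff * diff).sum(axis=1).mean()
    ce = zc_logits.cross_entropy(np.argmax(z_c, axis=1))
    reg = loss_config.beta_n * mse + loss_config.beta_c * ce

    adversarial = float(term_real.data + term_fake.data)
    d_loss = -(term_real + term_fake)
    ge_loss = term_fake + reg
    return ClusterGANLosses(d_loss=d_loss, ge_loss=ge_loss,
                            adversarial=adversarial,
                            regularizer=float(reg.data),
                            objective=adversarial + float(reg.data))


def local_train_clustergan(model: ClusterGANModel, data: ClientDataset,
                           prior: LatentPrior, loss_config: LossConfig,
                           epochs: int = 5, batch: int = 32, lr: float = 5e-4,
                           rng: np.random.Generator | None = None) -> ClusterGANModel:
    """Alternating local steps: one D update then one (G,E) update per batch."""
    if len(data) == 0:
        raise ValueError("empty client dataset")
    if rng is None:
        rng = np.random.default_rng(0)
    flat = data.images.reshape(len(data), -1)
    opt_d = nn.SGD(model.D.parameters(), lr=lr)
    ge_params: "OrderedDict[str, nn.Tensor]" = OrderedDict()
    ge_params.update(model.G.parameters())
    ge_params.update(model.E.parameters())
    opt_ge = nn.SGD(ge_params, lr=lr)

    for _ in range(epochs):
        order = rng.permutation(len(data))
        for start in range(0, len(data), batch):
            idx = order[start:start + batch]
            real = flat[idx]
            z_n, z_c = sample_latent(len(idx), prior, rng)

            losses = clustergan_losses(real, (z_n, z_c), model, loss_config)
            if not np.isfinite(losses.d_loss.data):
                raise FloatingPointError("ClusterGAN discriminator loss diverged")
            opt_d.zero_grad()
            opt_ge.zero_grad()
            losses.d_loss.backward()
            opt_d.step()

            losses = clustergan_losses(real, (z_n, z_c), model, loss_config)
            if not np.isfinite(losses.ge_loss.data):
                raise FloatingPointError("ClusterGAN generator/encoder loss diverged")
            opt_d.zero_grad()
            opt_ge.zero_grad()
            losses.ge_loss.backward()
            opt_ge.step()
    return model


def federated_train_clustergan(clients: Sequence[ClientDataset], prior: LatentPrior,
                               loss_config: LossConfig, train_config: TrainConfig,
                               epochs: int = 5, lr: float = 5e-4,
                               hidden: int = 64) -> ClusterGANModel:
    """Train G, D and E federatedly: all three parameter sets are averaged."""
    if len(clients) == 0:
        raise ValueError("no clients")
    image_size = clients[0].images.shape[1]
    model = ClusterGANModel(image_size, prior, loss_config.quality_mode,
                            hidden=hidden, seed=train_config.seed)

    index_of = {id(c): i for i, c in enumerate(clients)}

    def local_step(client, global_params, rnd):
        model.set_params(global_params)
        idx = index_of[id(client)]
        rng = np.random.default_rng(
            np.random.SeedSequence([train_config.seed, rnd, idx]).generate_state(1)[0])
        local_train_clustergan(model, client, prior, loss_config,
                               epochs=epochs, batch=train_config.batch_size,
                               lr=lr, rng=rng)
        return model.get_params()

    final, _ = run_rounds(list(clients), model.get_params(), train_config,
                          local_step, monitor_metric=None)
    model.set_params(final)
    return model


def encode(model: ClusterGANModel, images: np.ndarray) -> np.ndarray:
    """Latent codes: concatenated (zn_hat, softmax(zc logits)) per image."""
    images = np.asarray(images)
    expect = model.image_size * model.image_size
    flat = images.reshape(len(images), -1)
    if flat.shape[1] != expect:
        raise ValueError("image shape does not match the trained model")
    out = model.E(nn.Tensor(flat))
    dzn = model.prior.dim_zn
    zn = out.data[:, :dzn]
    logits = out.data[:, dzn:]
    shifted = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)
    return np.concatenate([zn, probs], axis=1)


@dataclass
class DomainAssignment:
    """Per-client per-sample domain labels (1-based) plus latent centroids."""

    labels: "OrderedDict[str, np.ndarray]"
    centroids: np.ndarray   # (K, latent_dim)
    K: int

    def assign_new(self, codes: np.ndarray) -> np.ndarray:
        """Nearest-centroid (Euclidean) domain labels for unseen codes."""
        d2 = ((codes[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1) + 1

    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        import pandas as pd
        for cid, lab in self.labels.items():
            pd.DataFrame({"sample_index": np.arange(len(lab)), "domain": lab}
                         ).to_csv(directory / f"domains_{cid}.csv", index=False)
        np.savetxt(directory / "centroids.csv", self.centroids, delimiter=",")


def assign_domains(global_model: ClusterGANModel, clients: Sequence[ClientDataset],
                   K: int, seed: int = 0) -> DomainAssignment:
    """K-Means (Euclidean) on pooled encoded codes of all clients.

    Cluster labels are canonicalized by descending cluster size so the
    assignment is deterministic up to the seeded k-means++ run.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    codes = [encode(global_model, c.images) for c in clients]
    pooled = np.concatenate(codes, axis=0)
    if len(np.unique(pooled, axis=0)) < K:
        raise ValueError("fewer distinct latent codes than clusters requested")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(pooled)
    raw = km.labels_
    order = np.argsort(-np.bincount(raw, minlength=K), kind="stable")
    relabel = np.empty(K, dtype=np.intp)
    relabel[order] = np.arange(K)
    centroids = km.cluster_centers_[order]
    labels: "OrderedDict[str, np.ndarray]" = OrderedDict()
    pos = 0
    for c, code in zip(clients, codes):
        labels[str(c.client_id)] = relabel[raw[pos:pos + len(code)]] + 1
        pos += len(code)
    return DomainAssignment(labels=labels, centroids=centroids, K=K)
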
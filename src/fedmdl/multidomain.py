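"""Federated multi-domain classification.

A single CNN backbone with parameters theta is shared by all domains and
frozen after initialization; only the last fully connected layer is
domain-specific, with an independent parameter set phi_d (weights +
bias) per domain d in {1..K}. A sample with domain label d is scored by
head phi_d on the shared features — so the model is g(theta; phi) with
routing by domain label.

Training is federated per head: each round clients update the heads for
the domains they hold, and the server averages each phi_d across clients
weighted by the clients' domain-d sample counts. theta is broadcast
unchanged.

The desk-scale backbone is a frozen random *linear* convolutional
projection (two 3x3 convolution banks with average pooling, then a
linear map to feature_dim 32). Keeping the frozen features linear in the
pixels is deliberate: a single softmax head on them is then exactly a
linear classifier, so the conflicting-label pathology built by the
synthetic generator is provably out of reach of one global head while
per-domain heads fit it — comparisons against single-head baselines
measure domain routing, not backbone capacity.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .clustergan import ClusterGANModel, DomainAssignment, encode
from .federated import ParamVector, TrainConfig, aggregate
from .synthetic import ClientDataset

logger = logging.getLogger("fedmdl")

__all__ = [
    "MultiDomainModel",
    "build_model",
    "forward_routed",
    "local_train_multidomain",
    "federated_train_multidomain",
    "infer",
]

DESK_FEATURE_DIM = 32
_DESK_FILTERS = 8


def _conv2d_linear(x: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Valid 3x3 convolution bank, linear (no activation).

    x: (n, C, H, W); filters: (F, C, 3, 3) -> (n, F, H-2, W-2).
    """
    win = sliding_window_view(x, (3, 3), axis=(2, 3))    # (n, C, H-2, W-2, 3, 3)
    return np.einsum("nchwij,fcij->nfhw", win, filters)


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    h2, w2 = h - h % 2, w - w % 2
    x = x[:, :, :h2, :w2]
    return x.reshape(n, c, h2 // 2, 2, w2 // 2, 2).mean(axis=(3, 5))


@dataclass
class MultiDomainModel:
    theta: ParamVector                       # frozen backbone parameters
    phi: "OrderedDict[int, ParamVector]"     # 1-based domain -> head params
    K: int
    n_classes: int
    backbone_spec: str
    feature_dim: int

    def features(self, images: np.ndarray) -> np.ndarray:
        """Frozen-backbone features for a (n, H, W) image batch."""
        if self.backbone_spec != "desk":
            raise ValueError(f"unknown backbone spec {self.backbone_spec!r}")
        x = np.asarray(images, dtype=np.float64)[:, None, :, :]
        x = _avgpool2(_conv2d_linear(x, self.theta["conv1"]))
        x = _avgpool2(_conv2d_linear(x, self.theta["conv2"]))
        flat = x.reshape(len(x), -1)
        return flat @ self.theta["proj"]

    def head(self, d: int) -> tuple[np.ndarray, np.ndarray]:
        pv = self.phi[d]
        return pv["W"], pv["b"]

    def copy(self) -> "MultiDomainModel":
        return MultiDomainModel(self.theta.copy(),
                                OrderedDict((d, p.copy()) for d, p in self.phi.items()),
                                self.K, self.n_classes, self.backbone_spec,
                                self.feature_dim)

    def theta_hash(self) -> int:
        """Stable content hash of the frozen backbone (conservation checks)."""
        import hashlib
        h = hashlib.sha256()
        for name in self.theta.names():
            h.update(self.theta[name].tobytes())
        return int.from_bytes(h.digest()[:8], "big")


def build_model(backbone_spec: str, K: int, n_classes: int, seed: int,
                image_size: int = 16) -> MultiDomainModel:
    """Initialize a frozen backbone and K independent head parameter sets."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if backbone_spec == "resnet50":
        raise RuntimeError(
            "the resnet50 backbone spec requires a pretrained-CNN dependency "
            "that this build does not ship; use the 'desk' spec")
    if backbone_spec != "desk":
        raise ValueError(f"unknown backbone spec {backbone_spec!r}")
    rng = np.random.default_rng(seed)
    conv1 = rng.normal(0, 1.0 / 3.0, size=(_DESK_FILTERS, 1, 3, 3))
    conv2 = rng.normal(0, 1.0 / (3.0 * np.sqrt(_DESK_FILTERS)),
                       size=(_DESK_FILTERS, _DESK_FILTERS, 3, 3))
    # probe the conv stack to size the final projection
    probe = np.zeros((1, 1, image_size, image_size))
    out = _avgpool2(_conv2d_linear(_avgpool2(_conv2d_linear(probe, conv1)), conv2))
    flat_dim = out.reshape(1, -1).shape[1]
    proj = rng.normal(0, 1.0 / np.sqrt(flat_dim), size=(flat_dim, DESK_FEATURE_DIM))
    theta = ParamVector(OrderedDict([("conv1", conv1), ("conv2", conv2),
                                     ("proj", proj)]),
                        {"conv1": False, "conv2": False, "proj": False})
    phi: "OrderedDict[int, ParamVector]" = OrderedDict()
    for d in range(1, K + 1):
        W = rng.normal(0, 0.01, size=(DESK_FEATURE_DIM, n_classes))
        b = np.zeros(n_classes)
        phi[d] = ParamVector(OrderedDict([("W", W), ("b", b)]))
    return MultiDomainModel(theta=theta, phi=phi, K=K, n_classes=n_classes,
                            backbone_spec=backbone_spec,
                            feature_dim=DESK_FEATURE_DIM)


def forward_routed(model: MultiDomainModel, images: np.ndarray,
                   domain_labels: np.ndarray,
                   features: np.ndarray | None = None) -> np.ndarray:
    """Class logits: frozen features through each sample's domain head."""
    domain_labels = np.asarray(domain_labels)
    if np.any((domain_labels < 1) | (domain_labels > model.K)):
        raise ValueError("domain labels must lie in {1..K}")
    f = model.features(images) if features is None else features
    logits = np.empty((len(f), model.n_classes))
    for d in np.unique(domain_labels):
        mask = domain_labels == d
        W, b = model.head(int(d))
        logits[mask] = f[mask] @ W + b
    return logits


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def local_train_multidomain(model: MultiDomainModel, data: ClientDataset,
                            domain_labels: np.ndarray, epochs: int = 20,
                            batch: int = 32, lr: float = 1e-3,
                            momentum: float = 0.9, weight_decay: float = 1e-4,
                            rng: np.random.Generator | None = None
                            ) -> MultiDomainModel:
    """Local SGD on the routed cross-entropy; only phi updates.

    Heads for domains absent from this client are left untouched, and
    theta is frozen by construction (it never enters the update).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    domain_labels = np.asarray(domain_labels)
    if len(domain_labels) != len(data):
        raise ValueError("one domain label per sample required")
    f = model.features(data.images)
    y = data.class_labels
    vel = {d: {"W": np.zeros_like(model.phi[d]["W"]),
               "b": np.zeros_like(model.phi[d]["b"])} for d in model.phi}
    n = len(data)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            m = len(idx)
            for d in np.unique(domain_labels[idx]):
                sub = idx[domain_labels[idx] == d]
                W, b = model.head(int(d))
                logits = f[sub] @ W + b
                p = _softmax(logits)
                if not np.all(np.isfinite(p)):
                    raise FloatingPointError("NaN in multi-domain training")
                p[np.arange(len(sub)), y[sub]] -= 1.0
                gW = f[sub].T @ p / m + weight_decay * W
                gb = p.sum(axis=0) / m + weight_decay * b
                vW, vb = vel[int(d)]["W"], vel[int(d)]["b"]
                vW *= momentum; vW += gW
                vb *= momentum; vb += gb
                model.phi[int(d)] = ParamVector(OrderedDict(
                    [("W", W - lr * vW), ("b", b - lr * vb)]))
    return model


def _aggregate_heads(models: Sequence[MultiDomainModel],
                     head_counts: Sequence[Mapping[int, int]],
                     reference: MultiDomainModel) -> MultiDomainModel:
    """Per-head weighted mean; weight = client's sample count in that domain."""
    out = reference.copy()
    for d in range(1, reference.K + 1):
        weights = [counts.get(d, 0) for counts in head_counts]
        if sum(weights) == 0:
            logger.warning("domain %d has no samples on any client; "
                           "head left at previous value", d)
            continue
        out.phi[d] = aggregate([m.phi[d] for m in models], weights)
    return out


def federated_train_multidomain(clients: Sequence[ClientDataset],
                                assignments: DomainAssignment,
                                train_config: TrainConfig,
                                model: MultiDomainModel | None = None,
                                epochs: int = 20, lr: float | None = None,
                                val_fraction: float = 0.1) -> MultiDomainModel:
    """Federated rounds with per-head aggregation and early stopping.

    Early stopping monitors pooled validation accuracy on a held-out
    `val_fraction` split of the training clients; the best-metric model
    is returned. theta never changes (hash-stable across the run).
    """
    if lr is None:
        lr = train_config.learning_rate
    if model is None:
        image_size = clients[0].images.shape[1]
        model = build_model("desk", assignments.K, 2, train_config.seed,
                            image_size=image_size)
    global_model = model.copy()
    theta_hash = global_model.theta_hash()

    rng = np.random.default_rng(train_config.seed)
    train_parts, val_feats, val_y, val_dom = [], [], [], []
    for c in clients:
        dom = assignments.labels[str(c.client_id)]
        idx = rng.permutation(len(c))
        n_val = int(np.floor(val_fraction * len(c)))
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        train_parts.append((c, tr_idx, dom))
        if n_val:
            val_feats.append(global_model.features(c.images[val_idx]))
            val_y.append(c.class_labels[val_idx])
            val_dom.append(dom[val_idx])
    val_feats = np.concatenate(val_feats) if val_feats else None

    def val_accuracy(m: MultiDomainModel) -> float:
        if val_feats is None:
            return 0.0
        logits = forward_routed(m, None, np.concatenate(val_dom), features=val_feats)
        return float(np.mean(logits.argmax(axis=1) == np.concatenate(val_y)))

    best_model = global_model.copy()
    best_metric = -np.inf
    stall = 0
    for rnd in range(1, train_config.max_rounds + 1):
        locals_, counts = [], []
        for i, (c, tr_idx, dom) in enumerate(train_parts):
            local = global_model.copy()
            sub = ClientDataset(images=c.images[tr_idx],
                                class_labels=c.class_labels[tr_idx],
                                client_id=c.client_id)
            seed = np.random.SeedSequence(
                [train_config.seed, rnd, i]).generate_state(1)[0]
            local_train_multidomain(local, sub, dom[tr_idx], epochs=epochs,
                                    batch=train_config.batch_size, lr=lr,
                                    momentum=train_config.momentum,
                                    weight_decay=train_config.weight_decay,
                                    rng=np.random.default_rng(seed))
            locals_.append(local)
            counts.append({int(d): int(np.sum(dom[tr_idx] == d))
                           for d in np.unique(dom[tr_idx])})
        global_model = _aggregate_heads(locals_, counts, global_model)
        metric = val_accuracy(global_model)
        if metric > best_metric:
            best_metric = metric
            best_model = global_model.copy()
            stall = 0
        else:
            stall += 1
            if stall >= train_config.early_stop_patience:
                break
    assert best_model.theta_hash() == theta_hash
    return best_model


def infer(model: MultiDomainModel, images: np.ndarray,
          assignment: DomainAssignment, encoder: ClusterGANModel,
          domain_labels: np.ndarray | None = None) -> np.ndarray:
    """Predicted classes for unseen images.

    Test-time domains come from the nearest latent centroid (Euclidean)
    of the federated ClusterGAN encoder; pass `domain_labels` to use
    oracle routing instead (testing mode).
    """
    if domain_labels is None:
        if assignment.centroids is None or len(assignment.centroids) == 0:
            raise ValueError("missing centroids for test-time domain routing")
        codes = encode(encoder, images)
        domain_labels = assignment.assign_new(codes)
    logits = forward_routed(model, images, domain_labels)
    return logits.argmax(axis=1)
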
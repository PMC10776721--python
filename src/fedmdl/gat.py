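"""Graph-based fine-tuning of the domain-specific heads.

The K per-domain head parameter sets phi_d are flattened into vertices
v_d in R^M of a complete graph (no self-loops: the neighborhood of d is
every vertex except d). A graph attention network transforms the
vertices, so domains borrow strength from one another through learned,
input-dependent edge weights. By default the network is trained in
residual form — the fine-tuned head is phi_d plus the GAT's attended
output, so an untrained GAT leaves the heads essentially unchanged and
training learns a cross-domain correction; set ``residual=False`` to
replace phi_d by v-hat_d outright.

Attention coefficients per head follow

    e_dj = softmax_j( LeakyReLU( score(W v_d, W v_j) ) ),  j in N_d

with two score functions: the literal concat-linear form
a . [W v_d (+) W v_j], and the default scaled-cosine form
cos(a (*) W v_d, W v_j) / tau — the dot product replaced by a cosine so
scores stay in a bounded range and gradients do not vanish with vertex
scale. Each layer's output is the multi-head *average*

    v-hat_d = sigma( (1/L) sum_l sum_{j in N_d} e^l_dj W^l v_j )

with sigma = ELU, stacked n_layers deep with hidden width M.

Fine-tuning is client-local: with the graph built from the global heads,
each client trains its own GAT parameters to minimize the routed
classification cross-entropy of the reconstructed heads on its data
(gradients flow through the GAT only; phi and theta stay fixed), then
the fine-tuned heads are aggregated across clients by domain sample
counts. A GCN variant fixes every edge weight at 1/|N_d|, removing the
attention mechanism but keeping the rest of the pipeline identical.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .clustergan import DomainAssignment
from .federated import ParamVector
from .multidomain import MultiDomainModel
from .synthetic import ClientDataset

__all__ = [
    "DomainGraph",
    "GATConfig",
    "GATParams",
    "build_domain_graph",
    "flatten_head",
    "unflatten_head",
    "attention_coeffs",
    "gat_forward",
    "finetune_phi",
    "gcn_variant",
]


# ------------------------------------------------------------------ flattening

def flatten_head(pv: ParamVector) -> np.ndarray:
    """Deterministic head flattening: weight matrix raveled, then bias."""
    return np.concatenate([pv["W"].ravel(), pv["b"].ravel()])


def unflatten_head(vec: np.ndarray, feature_dim: int, n_classes: int) -> ParamVector:
    W = vec[:feature_dim * n_classes].reshape(feature_dim, n_classes)
    b = vec[feature_dim * n_classes:]
    return ParamVector(OrderedDict([("W", W.copy()), ("b", b.copy())]))


@dataclass
class DomainGraph:
    """Complete graph over flattened per-domain heads."""

    vertices: np.ndarray     # (K, M)
    feature_dim: int
    n_classes: int

    @property
    def K(self) -> int:
        return len(self.vertices)

    @property
    def M(self) -> int:
        return self.vertices.shape[1]


def build_domain_graph(phi: Mapping[int, ParamVector], feature_dim: int,
                       n_classes: int) -> DomainGraph:
    if len(phi) < 2:
        raise ValueError("need K >= 2 domains to build a graph (no neighbors)")
    vecs = [flatten_head(phi[d]) for d in sorted(phi)]
    if len({v.shape for v in vecs}) != 1:
        raise ValueError("heads must share one shape")
    return DomainGraph(vertices=np.stack(vecs), feature_dim=feature_dim,
                       n_classes=n_classes)


# ---------------------------------------------------------------------- config

@dataclass
class GATConfig:
    n_layers: int = 5
    n_heads: int = 5                   # attention heads L per layer
    dropout: float = 0.2
    similarity: str = "scaled-cosine"  # scaled-cosine | concat-linear | uniform
    cosine_temperature: float = 0.5
    cosine_eps: float = 0.0            # >0 enables the zero-norm guard
    residual: bool = True              # phi'_d = phi_d + vhat_d (correction form)
    leaky_relu_slope: float = 0.2
    lr: float = 5e-4
    epochs: int = 5
    batch_size: int = 32
    seed: int = 42

    def __post_init__(self):
        if self.n_heads < 1:
            raise ValueError("need at least one attention head")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0,1)")
        if self.cosine_temperature <= 0:
            raise ValueError("cosine temperature must be positive")
        if self.similarity not in ("scaled-cosine", "concat-linear", "uniform"):
            raise ValueError(f"unknown similarity {self.similarity!r}")


class GATParams(nn.Module):
    """Per-layer, per-head weight matrices W and attention vectors a."""

    def __init__(self, M: int, config: GATConfig, seed: int | None = None):
        rng = np.random.default_rng(config.seed if seed is None else seed)
        self.config = config
        self.M = M
        self.W: list[list[nn.Tensor]] = []
        self.a: list[list[nn.Tensor]] = []
        a_dim = 2 * M if config.similarity == "concat-linear" else M
        for layer in range(config.n_layers):
            Ws, As = [], []
            for head in range(config.n_heads):
                Ws.append(nn.Tensor(nn.xavier_init(rng, M, M), requires_grad=True))
                if config.similarity == "uniform":
                    As.append(None)
                else:
                    As.append(nn.Tensor(
                        nn.xavier_init(rng, a_dim, 1).ravel(), requires_grad=True))
            self.W.append(Ws)
            self.a.append(As)

    def parameters(self):
        out: "OrderedDict[str, nn.Tensor]" = OrderedDict()
        for l, (Ws, As) in enumerate(zip(self.W, self.a)):
            for h, (W, a) in enumerate(zip(Ws, As)):
                out[f"W.{l}.{h}"] = W
                if a is not None:
                    out[f"a.{l}.{h}"] = a
        return out


# ------------------------------------------------------------------- attention

def attention_coeffs(vertices, W, a, config: GATConfig) -> nn.Tensor:
    """Normalized attention coefficients for one head on one layer.

    Returns a K x K tensor whose row d is a softmax over the neighbors
    j != d (the diagonal is exactly 0). `vertices` may be an array or a
    Tensor of shape (K, M).
    """
    V = nn.as_tensor(vertices)
    K = V.shape[0]
    if K < 2:
        raise ValueError("need at least 2 vertices")
    H = V @ W if W is not None else V
    if config.similarity == "uniform":
        e = np.full((K, K), 1.0 / (K - 1))
        np.fill_diagonal(e, 0.0)
        return nn.Tensor(e)
    if config.similarity == "concat-linear":
        h = H.shape[1]
        a1 = a.reshape(1, -1).cols(0, h).reshape(-1, 1)
        a2 = a.reshape(1, -1).cols(h, 2 * h).reshape(-1, 1)
        left = H @ a1            # (K, 1)
        right = (H @ a2).T       # (1, K)
        scores = (left + right).leaky_relu(config.leaky_relu_slope)
    else:  # scaled-cosine
        U = H * a.reshape(1, -1)
        norms_u = ((U * U).sum(axis=1, keepdims=True) + 1e-300) ** 0.5
        norms_h = ((H * H).sum(axis=1, keepdims=True) + 1e-300) ** 0.5
        if config.cosine_eps > 0:
            norms_u = norms_u + config.cosine_eps
            norms_h = norms_h + config.cosine_eps
        elif np.any(norms_u.data < 1e-12) or np.any(norms_h.data < 1e-12):
            raise ValueError(
                "zero-norm transformed vertex in scaled-cosine attention; "
                "set cosine_eps > 0 to enable the epsilon-norm guard")
        cos = (U / norms_u) @ (H / norms_h).T
        scores = (cos / config.cosine_temperature).leaky_relu(config.leaky_relu_slope)
    mask = np.zeros((K, K))
    np.fill_diagonal(mask, -1e30)
    return (scores + nn.Tensor(mask)).softmax(axis=1)


def _dropout(t: nn.Tensor, p: float, rng: np.random.Generator) -> nn.Tensor:
    keep = (rng.random(t.shape) >= p).astype(np.float64) / (1.0 - p)
    return t * nn.Tensor(keep)


def gat_forward(graph: DomainGraph | np.ndarray, params: GATParams,
                config: GATConfig, training: bool = False,
                rng: np.random.Generator | None = None) -> nn.Tensor:
    """Stacked multi-head attention layers over the domain graph.

    Per layer: v-hat_d = ELU( (1/L) sum_l sum_j e^l_dj W^l v_j ), hidden
    width M throughout, so the final output has the head shape. Dropout
    (on inputs and attention coefficients) is active only in training
    mode; evaluation is deterministic.
    """
    V = nn.as_tensor(graph.vertices if isinstance(graph, DomainGraph) else graph)
    if training and config.dropout > 0 and rng is None:
        rng = np.random.default_rng(config.seed)
    for layer in range(config.n_layers):
        x = V
        if training and config.dropout > 0:
            x = _dropout(x, config.dropout, rng)
        head_outputs = []
        for head in range(config.n_heads):
            W = params.W[layer][head]
            a = params.a[layer][head]
            e = attention_coeffs(x, W, a, config)
            if training and config.dropout > 0:
                e = _dropout(e, config.dropout, rng)
            head_outputs.append(e @ (x @ W))
        total = head_outputs[0]
        for ho in head_outputs[1:]:
            total = total + ho
        V = (total / float(config.n_heads)).elu()
    return V


# ------------------------------------------------------------------ fine-tuning

def _client_gat_train(graph: DomainGraph, feats: np.ndarray, labels: np.ndarray,
                      domains: np.ndarray, config: GATConfig,
                      seed: int) -> np.ndarray:
    """Train one client's GAT on its routed cross-entropy; return V-hat."""
    params = GATParams(graph.M, config, seed=seed)
    opt = nn.SGD(params.parameters(), lr=config.lr)
    rng = np.random.default_rng(seed)
    F, C = graph.feature_dim, graph.n_classes
    n = len(feats)
    base = nn.Tensor(graph.vertices)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            vhat = gat_forward(graph, params, config, training=True, rng=rng)
            if config.residual:
                vhat = base + vhat
            loss = None
            m = len(idx)
            for d in np.unique(domains[idx]):
                sub = idx[domains[idx] == d]
                row = vhat.rows(np.asarray([d - 1]))
                Wd = row.cols(0, F * C).reshape(F, C)
                bd = row.cols(F * C, graph.M)
                logits = nn.Tensor(feats[sub]) @ Wd + bd
                term = logits.cross_entropy(labels[sub]) * (len(sub) / m)
                loss = term if loss is None else loss + term
            if loss is None:
                continue
            if not np.isfinite(loss.data):
                raise FloatingPointError("NaN loss in GAT fine-tuning")
            opt.zero_grad()
            loss.backward()
            opt.step()
    out = gat_forward(graph, params, config, training=False).data
    return graph.vertices + out if config.residual else out


def finetune_phi(model: MultiDomainModel, clients: Sequence[ClientDataset],
                 assignments: DomainAssignment, gat_config: GATConfig,
                 ) -> "OrderedDict[int, ParamVector]":
    """Client-local GAT fine-tuning of the global heads, then aggregation.

    Returns the fine-tuned head set phi'; heads for domains with no
    samples anywhere keep their pre-fine-tuning values. With K < 2 the
    graph has no neighbors and fine-tuning is skipped with a warning.
    """
    import logging
    if model.K < 2:
        logging.getLogger("fedmdl").warning(
            "K < 2: no domain graph, fine-tuning skipped")
        return OrderedDict((d, p.copy()) for d, p in model.phi.items())
    graph = build_domain_graph(model.phi, model.feature_dim, model.n_classes)
    vhat_list, weight_list = [], []
    for i, c in enumerate(clients):
        dom = np.asarray(assignments.labels[str(c.client_id)])
        feats = model.features(c.images)
        seed = int(np.random.SeedSequence(
            [gat_config.seed, i]).generate_state(1)[0])
        if gat_config.epochs == 0:
            params = GATParams(graph.M, gat_config, seed=seed)
            vhat = gat_forward(graph, params, gat_config, training=False).data
            if gat_config.residual:
                vhat = graph.vertices + vhat
        else:
            vhat = _client_gat_train(graph, feats, c.class_labels, dom,
                                     gat_config, seed)
        vhat_list.append(vhat)
        weight_list.append({int(d): int(np.sum(dom == d)) for d in np.unique(dom)})

    phi_prime: "OrderedDict[int, ParamVector]" = OrderedDict()
    for d in range(1, model.K + 1):
        weights = np.array([w.get(d, 0) for w in weight_list], dtype=np.float64)
        if weights.sum() == 0:
            phi_prime[d] = model.phi[d].copy()
            continue
        weights /= weights.sum()
        vec = sum(w * v[d - 1] for w, v in zip(weights, vhat_list))
        phi_prime[d] = unflatten_head(vec, model.feature_dim, model.n_classes)
    return phi_prime


def gcn_variant(model: MultiDomainModel, clients: Sequence[ClientDataset],
                assignments: DomainAssignment, config: GATConfig,
                ) -> "OrderedDict[int, ParamVector]":
    """GCN ablation: identical pipeline with fixed uniform neighbor weights."""
    from dataclasses import replace
    return finetune_phi(model, clients, assignments,
                        replace(config, similarity="uniform"))
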
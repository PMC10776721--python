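"""Desk-scale experiment harness: baselines, proposed pipeline, ablations.

Five methods are compared on synthetic federations with held-out test
clients:

- ``fedavg``: one global head (K = 1), plain federated averaging — no
  notion of domains.
- ``cluster_fl``: client-level clustering. Each client is represented by
  its mean latent code from the federated ClusterGAN encoder; clients
  are grouped by K-Means (cluster count chosen by the same silhouette
  search applied to the client representatives) and FedAvg runs
  independently inside each group. Test clients are routed to the
  nearest client-cluster centroid. This addresses inter-client but not
  intra-client heterogeneity.
- ``proposed``: the full pipeline — domain-number estimation, federated
  ClusterGAN domain assignment, federated multi-domain training, GAT
  fine-tuning of the heads, nearest-centroid domain routing at test
  time.
- ``proposed_no_gnn`` / ``proposed_gcn``: ablations of the fine-tuning
  stage (none, or uniform-weight GCN instead of attention).

All five share every code path except their defining difference: per
seed the federation, the trained ClusterGAN, the domain assignment and
the trained multi-domain model are computed once and reused, so the
comparison is controlled.
"""

from __future__ import annotations

import json
import logging
from collections import OrderedDict
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .clustergan import (DomainAssignment, LatentPrior, LossConfig,
                         assign_domains, encode, federated_train_clustergan)
from .domain_search import (DomainSearchConfig, cluster_purity,
                            estimate_domain_number)
from .federated import Metrics, TrainConfig, evaluate
from .gat import GATConfig, finetune_phi, gcn_variant
from .multidomain import (MultiDomainModel, build_model,
                          federated_train_multidomain, forward_routed, infer)
from .synthetic import (ClientDataset, FederatedDataset, SyntheticConfig,
                        dominant_mixtures, generate_federation)

logger = logging.getLogger("fedmdl")

METHODS = ("fedavg", "cluster_fl", "proposed", "proposed_no_gnn", "proposed_gcn")

__all__ = [
    "ExperimentConfig",
    "METHODS",
    "make_federation",
    "run_fedavg",
    "run_cluster_fl",
    "run_proposed",
    "run_all_methods",
    "run_comparison",
    "report",
]


@dataclass
class ExperimentConfig:
    """One experiment: data conditions + per-stage settings.

    The defaults are the desk-scale benchmark: 8 training and 4 held-out
    test clients of 150 16x16 images each, three true domains mixed
    0.85/0.075/0.075 per client, conflicting label rules across domains
    — the intra-client-heterogeneity pathology at a size that runs on a
    single CPU. (The case-study-shaped 11/4-client split over beat
    images is expressible with the same fields.)
    """

    n_train_clients: int = 8
    n_test_clients: int = 4
    n_domains_true: int = 3
    samples_per_client: int = 150
    image_size: int = 16
    template_contrast: float = 1.0
    noise_sd: float = 0.05
    conflicting_labels: bool = True
    dominant_mixture: float = 0.7
    dataset_dir: str | None = None    # preprocessed FederatedDataset instead

    method: str = "proposed"
    seed: int = 42
    repeats: int = 10

    # stage settings (desk-scale)
    search: DomainSearchConfig = field(default_factory=lambda: DomainSearchConfig(
        max_domains=6, patience=2, search_epochs=1, search_rounds=2))
    loss: LossConfig = field(default_factory=LossConfig)
    gan_rounds: int = 3
    gan_epochs: int = 2
    gan_lr: float = 5e-4
    heads: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=0.03, batch_size=32, max_rounds=30, early_stop_patience=5))
    head_epochs: int = 20
    gat: GATConfig = field(default_factory=lambda: GATConfig(
        lr=5e-3, epochs=5, cosine_eps=1e-8))
    dim_zn: int = 30
    sigma: float = 0.1

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, sub in (("search", DomainSearchConfig), ("loss", LossConfig),
                         ("heads", TrainConfig), ("gat", GATConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path):
        import yaml
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


def make_federation(config: ExperimentConfig, seed: int
                    ) -> tuple[list[ClientDataset], list[ClientDataset], FederatedDataset]:
    """Generate (or load) the federation and split off the test clients."""
    if config.dataset_dir is not None:
        fed = FederatedDataset.load(config.dataset_dir)
    else:
        n = config.n_train_clients + config.n_test_clients
        mix = dominant_mixtures(n, config.n_domains_true, config.dominant_mixture)
        fed = generate_federation(SyntheticConfig(
            n_clients=n, n_domains_true=config.n_domains_true,
            samples_per_client=config.samples_per_client,
            image_size=config.image_size, domain_mixture=mix,
            template_contrast=config.template_contrast,
            noise_sd=config.noise_sd,
            conflicting_labels=config.conflicting_labels, seed=seed))
    train = fed.clients[:config.n_train_clients]
    test = fed.clients[config.n_train_clients:
                       config.n_train_clients + config.n_test_clients]
    return train, test, fed


# ------------------------------------------------------------- shared stages

@dataclass
class PipelineState:
    """Stages shared by the proposed variants and cluster_fl for one seed."""

    search_result: object
    gan_model: object
    assignment: DomainAssignment
    md_model: MultiDomainModel
    purity: float


def _train_pipeline(train_clients: Sequence[ClientDataset],
                    config: ExperimentConfig, seed: int) -> PipelineState:
    search = replace(config.search, seed=seed)
    result = estimate_domain_number(
        train_clients, search, loss_config=config.loss,
        train_config=replace(config.heads, learning_rate=config.gan_lr, seed=seed),
        prior_dim_zn=config.dim_zn, prior_sigma=config.sigma)
    prior = LatentPrior(K=result.best_num, dim_zn=config.dim_zn, sigma=config.sigma)
    gan_cfg = TrainConfig(learning_rate=config.gan_lr,
                          batch_size=config.heads.batch_size,
                          max_rounds=config.gan_rounds,
                          early_stop_patience=min(5, config.gan_rounds), seed=seed)
    gan = federated_train_clustergan(train_clients, prior, config.loss, gan_cfg,
                                     epochs=config.gan_epochs, lr=config.gan_lr)
    assignment = assign_domains(gan, train_clients, result.best_num, seed=seed)
    purity = float("nan")
    if all(c.true_domains is not None for c in train_clients):
        assigned = np.concatenate([assignment.labels[str(c.client_id)]
                                   for c in train_clients])
        truth = np.concatenate([c.true_domains for c in train_clients])
        purity = cluster_purity(assigned, truth)
    heads_cfg = replace(config.heads, seed=seed)
    md = federated_train_multidomain(train_clients, assignment, heads_cfg,
                                     epochs=config.head_epochs)
    return PipelineState(result, gan, assignment, md, purity)


def _uniform_assignment(clients: Sequence[ClientDataset]) -> DomainAssignment:
    labels = OrderedDict((str(c.client_id), np.ones(len(c), dtype=np.intp))
                         for c in clients)
    return DomainAssignment(labels=labels, centroids=np.zeros((1, 1)), K=1)


def run_fedavg(config: ExperimentConfig, seed: int | None = None,
               data=None) -> Metrics:
    """Single-head FedAvg baseline (K = 1, no domain structure)."""
    seed = config.seed if seed is None else seed
    train, test, _ = make_federation(config, seed) if data is None else data
    assignment = _uniform_assignment(train)
    heads_cfg = replace(config.heads, seed=seed)
    model = federated_train_multidomain(train, assignment, heads_cfg,
                                        epochs=config.head_epochs)

    def predict(ds):
        return forward_routed(model, ds.images,
                              np.ones(len(ds), dtype=np.intp)).argmax(axis=1)

    return evaluate(predict, test)


def _client_cluster_count(reps: np.ndarray, search: DomainSearchConfig,
                          seed: int) -> int:
    """Silhouette search over client representatives."""
    upper = min(search.max_domains, len(reps) - 1)

    def scorer(k: int) -> float:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(reps)
        if len(np.unique(km.labels_)) < 2:
            return 0.0
        return float(np.mean(silhouette_samples(reps, km.labels_)))

    cfg = DomainSearchConfig(min_domains=2, max_domains=max(2, upper),
                             patience=search.patience, seed=seed)
    result = estimate_domain_number(
        [ClientDataset(images=np.zeros((len(reps), 8, 8)),
                       class_labels=np.zeros(len(reps), dtype=np.intp),
                       client_id="reps")],
        cfg, scorer=scorer)
    return result.best_num


def run_cluster_fl(config: ExperimentConfig, seed: int | None = None,
                   data=None, state: PipelineState | None = None) -> Metrics:
    """Cluster-based FL baseline: FedAvg within client-level clusters."""
    seed = config.seed if seed is None else seed
    train, test, _ = make_federation(config, seed) if data is None else data
    if len(train) < 2:
        raise ValueError("cluster-based FL needs at least 2 training clients")
    if state is None:
        state = _train_pipeline(train, config, seed)
    reps = np.stack([encode(state.gan_model, c.images).mean(axis=0) for c in train])
    n_clusters = _client_cluster_count(reps, config.search, seed)
    if n_clusters > len(train):
        raise ValueError("more client clusters than clients")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(reps)

    heads_cfg = replace(config.heads, seed=seed)
    cluster_models = {}
    for cl in range(n_clusters):
        members = [c for c, lab in zip(train, km.labels_) if lab == cl]
        if not members:
            continue
        assignment = _uniform_assignment(members)
        cluster_models[cl] = federated_train_multidomain(
            members, assignment, heads_cfg, epochs=config.head_epochs)

    def predict(ds):
        rep = encode(state.gan_model, ds.images).mean(axis=0)
        cl = int(np.argmin(((km.cluster_centers_ - rep) ** 2).sum(axis=1)))
        model = cluster_models[cl]
        return forward_routed(model, ds.images,
                              np.ones(len(ds), dtype=np.intp)).argmax(axis=1)

    return evaluate(predict, test)


def run_proposed(config: ExperimentConfig, seed: int | None = None,
                 data=None, state: PipelineState | None = None,
                 variant: str = "gat") -> Metrics:
    """Full pipeline; variant in {'gat', 'none', 'gcn'} picks the ablation."""
    seed = config.seed if seed is None else seed
    train, test, _ = make_federation(config, seed) if data is None else data
    if state is None:
        state = _train_pipeline(train, config, seed)
    model = state.md_model
    if model.K >= 2 and variant in ("gat", "gcn"):
        gat_cfg = replace(config.gat, seed=seed)
        fn = finetune_phi if variant == "gat" else gcn_variant
        phi_prime = fn(model, train, state.assignment, gat_cfg)
        model = model.copy()
        model.phi = phi_prime

    def predict(ds):
        return infer(model, ds.images, state.assignment, state.gan_model)

    return evaluate(predict, test)


def run_all_methods(config: ExperimentConfig, seed: int | None = None
                    ) -> tuple["OrderedDict[str, Metrics]", PipelineState]:
    """All five methods on one seed, sharing the trained stages."""
    seed = config.seed if seed is None else seed
    data = make_federation(config, seed)
    state = _train_pipeline(data[0], config, seed)
    out: "OrderedDict[str, Metrics]" = OrderedDict()
    out["fedavg"] = run_fedavg(config, seed, data=data)
    out["cluster_fl"] = run_cluster_fl(config, seed, data=data, state=state)
    out["proposed_no_gnn"] = run_proposed(config, seed, data=data, state=state,
                                          variant="none")
    out["proposed_gcn"] = run_proposed(config, seed, data=data, state=state,
                                       variant="gcn")
    out["proposed"] = run_proposed(config, seed, data=data, state=state,
                                   variant="gat")
    return out, state


def run_comparison(config: ExperimentConfig, methods: Sequence[str] | None = None
                   ) -> pd.DataFrame:
    """repeats x methods grid; repeat r uses seed config.seed + r."""
    rows = []
    for r in range(config.repeats):
        seed = config.seed + r
        results, state = run_all_methods(config, seed)
        for method, m in results.items():
            if methods is not None and method not in methods:
                continue
            rows.append({"seed": seed, "method": method,
                         "overall_accuracy": m.overall_accuracy,
                         "overall_f1": m.overall_f1,
                         "best_num": state.search_result.best_num,
                         "purity": state.purity})
    return pd.DataFrame(rows)


def report(results: pd.DataFrame | Sequence[Metrics], out_dir=None) -> pd.DataFrame:
    """Mean +/- sd comparison table; optionally written as CSV/JSON/text."""
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame([
            {"seed": i, "method": "run", "overall_accuracy": m.overall_accuracy,
             "overall_f1": m.overall_f1} for i, m in enumerate(results)])
    table = results.groupby("method").agg(
        accuracy_mean=("overall_accuracy", "mean"),
        accuracy_sd=("overall_accuracy", "std"),
        f1_mean=("overall_f1", "mean"),
        f1_sd=("overall_f1", "std"),
        n_runs=("overall_accuracy", "size")).reset_index()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "runs.csv", index=False)
        table.to_csv(out_dir / "comparison.csv", index=False)
        (out_dir / "comparison.json").write_text(
            json.dumps(table.to_dict(orient="records"), indent=2))
        (out_dir / "comparison.txt").write_text(table.to_string(index=False) + "\n")
    return table
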
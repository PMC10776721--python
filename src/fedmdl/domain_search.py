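"""Data-driven estimation of the number of domains K.

The search is incremental: starting from min_domains, each candidate
NumDomain gets its own federated ClusterGAN (the one-hot prior dimension
depends on K) trained at reduced epochs, samples are assigned domains by
pooled K-Means, and clustering quality is scored by the average
Silhouette across clients — each client's Silhouette is computed on its
own latent codes with its sample domain labels, and the client scores
are averaged unweighted. BestNum tracks the highest average score;
the search stops after `patience` consecutive candidates without
improvement, or at max_domains. The caller then re-trains the federated
ClusterGAN at K = BestNum with full epochs for the final assignment.

The scorer is injectable so the search logic is testable independently
of GAN stochasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import silhouette_samples

from .clustergan import (LatentPrior, LossConfig, assign_domains, encode,
                         federated_train_clustergan)
from .federated import TrainConfig
from .synthetic import ClientDataset

__all__ = [
    "DomainSearchConfig",
    "DomainSearchResult",
    "average_silhouette",
    "estimate_domain_number",
    "cluster_purity",
]


@dataclass
class DomainSearchConfig:
    min_domains: int = 2
    max_domains: int = 10
    patience: int = 2
    search_epochs: int = 1      # reduced ClusterGAN epochs per candidate K
    search_rounds: int = 2      # communication rounds per candidate K
    seed: int = 42

    def __post_init__(self):
        if not (2 <= self.min_domains <= self.max_domains):
            raise ValueError("need 2 <= min_domains <= max_domains")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class DomainSearchResult:
    best_num: int
    max_score: float
    trace: list[tuple[int, float]]
    stopped_early: bool

    def save(self, path):
        import json
        import pandas as pd
        path = Path(path)
        best = -np.inf
        rows = []
        for k, s in self.trace:
            improved = s > best
            best = max(best, s)
            rows.append({"NumDomain": k, "score_avg": s, "improved": improved})
        pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)
        path.with_suffix(".json").write_text(json.dumps(
            {"best_num": self.best_num, "max_score": self.max_score,
             "stopped_early": self.stopped_early, "trace": self.trace}))


def average_silhouette(per_client_codes: Sequence[np.ndarray],
                       per_client_labels: Sequence[np.ndarray]) -> float:
    """Unweighted client mean of per-client Silhouette scores (Euclidean).

    Convention for degenerate cases: samples in singleton clusters score
    0, and a client whose samples all carry one label contributes 0.
    """
    if len(per_client_codes) == 0:
        raise ValueError("no clients")
    scores = []
    for codes, labels in zip(per_client_codes, per_client_labels):
        codes = np.asarray(codes, dtype=np.float64)
        labels = np.asarray(labels)
        if len(codes) < 2:
            raise ValueError("each client needs at least 2 samples")
        if len(np.unique(labels)) < 2:
            scores.append(0.0)
            continue
        # silhouette_samples already scores singleton-cluster samples as 0
        scores.append(float(np.mean(silhouette_samples(codes, labels))))
    return float(np.mean(scores))


def _default_scorer(clients: Sequence[ClientDataset], num_domain: int,
                    search: DomainSearchConfig, loss_config: LossConfig,
                    train_config: TrainConfig, prior_dim_zn: int,
                    prior_sigma: float) -> float:
    prior = LatentPrior(K=num_domain, dim_zn=prior_dim_zn, sigma=prior_sigma)
    cfg = TrainConfig(learning_rate=train_config.learning_rate,
                      batch_size=train_config.batch_size,
                      max_rounds=search.search_rounds,
                      early_stop_patience=min(train_config.early_stop_patience,
                                              search.search_rounds),
                      seed=search.seed)
    model = federated_train_clustergan(clients, prior, loss_config, cfg,
                                       epochs=search.search_epochs)
    assignment = assign_domains(model, clients, num_domain, seed=search.seed)
    codes = [encode(model, c.images) for c in clients]
    labels = [assignment.labels[str(c.client_id)] for c in clients]
    return average_silhouette(codes, labels)


def estimate_domain_number(clients: Sequence[ClientDataset],
                           search_config: DomainSearchConfig,
                           loss_config: LossConfig | None = None,
                           train_config: TrainConfig | None = None,
                           scorer: Callable[[int], float] | None = None,
                           prior_dim_zn: int = 30, prior_sigma: float = 0.1,
                           ) -> DomainSearchResult:
    """Incremental Silhouette search for the number of domains.

    `scorer(num_domain) -> score_avg` may be injected; by default each
    candidate trains a reduced-epoch federated ClusterGAN and scores its
    pooled K-Means assignment.
    """
    if len(clients) == 0:
        raise ValueError("no clients")
    smallest = min(len(c) for c in clients)
    if search_config.max_domains > smallest:
        raise ValueError("max_domains exceeds the smallest client size")
    if scorer is None:
        if loss_config is None:
            loss_config = LossConfig()
        if train_config is None:
            train_config = TrainConfig(learning_rate=5e-4, batch_size=32)

        def scorer(k: int) -> float:
            return _default_scorer(clients, k, search_config, loss_config,
                                   train_config, prior_dim_zn, prior_sigma)

    best_num = search_config.min_domains
    max_score = -np.inf
    stall = 0
    trace: list[tuple[int, float]] = []
    stopped_early = False
    for num_domain in range(search_config.min_domains, search_config.max_domains + 1):
        score = float(scorer(num_domain))
        trace.append((num_domain, score))
        if score > max_score:
            max_score = score
            best_num = num_domain
            stall = 0
        else:
            stall += 1
            if stall >= search_config.patience:
                stopped_early = True
                break
    return DomainSearchResult(best_num=best_num, max_score=max_score,
                              trace=trace, stopped_early=stopped_early)


def cluster_purity(assigned: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of samples whose cluster's majority true domain is their own."""
    assigned = np.asarray(assigned)
    truth = np.asarray(truth)
    correct = 0
    for c in np.unique(assigned):
        members = truth[assigned == c]
        values, counts = np.unique(members, return_counts=True)
        correct += counts.max()
    return correct / len(truth)
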
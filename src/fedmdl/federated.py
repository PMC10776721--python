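"""Client/server federated-learning harness.

Simulates synchronous federated averaging: every round the server
broadcasts the global parameters, every client runs a local optimization
pass, and the server replaces the global model with the sample-count
weighted mean of the returns. All clients participate every round; there
is no transport, stragglers or client sampling — this is a single-process
simulation of the protocol.

The harness is model-agnostic: parameters travel as `ParamVector`s
(ordered name -> array maps with a per-name trainable mask), and the
local step is an injected callable, so the same loop trains the
ClusterGAN triple and the multi-domain classifier heads.
"""

from __future__ import annotations

import json
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import f1_score

logger = logging.getLogger("fedmdl")

__all__ = [
    "ParamVector",
    "TrainConfig",
    "Metrics",
    "local_train",
    "aggregate",
    "run_rounds",
    "evaluate",
]


class ParamVector:
    """Ordered map from parameter name to float array, with a trainable mask.

    Aggregation and arithmetic are only defined between vectors with
    identical names and shapes.
    """

    def __init__(self, named_tensors: Mapping[str, np.ndarray],
                 trainable_mask: Mapping[str, bool] | None = None):
        self.named_tensors: "OrderedDict[str, np.ndarray]" = OrderedDict(
            (k, np.asarray(v, dtype=np.float64)) for k, v in named_tensors.items())
        for k, v in self.named_tensors.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in parameter {k!r}")
        if trainable_mask is None:
            trainable_mask = {k: True for k in self.named_tensors}
        self.trainable_mask = dict(trainable_mask)

    def copy(self) -> "ParamVector":
        return ParamVector(OrderedDict((k, v.copy()) for k, v in self.named_tensors.items()),
                           dict(self.trainable_mask))

    def names(self):
        return list(self.named_tensors)

    def same_structure(self, other: "ParamVector") -> bool:
        return (self.names() == other.names()
                and all(self.named_tensors[k].shape == other.named_tensors[k].shape
                        for k in self.named_tensors))

    def flat(self) -> np.ndarray:
        return np.concatenate([v.ravel() for v in self.named_tensors.values()]) \
            if self.named_tensors else np.empty(0)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.named_tensors[name]

    def __len__(self):
        return len(self.named_tensors)

    def allclose(self, other: "ParamVector", tol: float = 0.0) -> bool:
        return self.same_structure(other) and all(
            np.allclose(self.named_tensors[k], other.named_tensors[k], atol=tol, rtol=0)
            for k in self.named_tensors)

    # -- persistence (named-tensor archive: .npz + JSON header alongside) ----
    def save(self, path):
        np.savez_compressed(path, **self.named_tensors)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"names": self.names(),
                       "trainable_mask": self.trainable_mask}, fh)

    @classmethod
    def load(cls, path) -> "ParamVector":
        with open(str(path) + ".json") as fh:
            header = json.load(fh)
        with np.load(path) as npz:
            tensors = OrderedDict((k, npz[k]) for k in header["names"])
        return cls(tensors, header["trainable_mask"])


@dataclass
class TrainConfig:
    """Federated optimization settings.

    Defaults follow the training protocol of the stress-prediction case
    study: SGD with momentum 0.9 and weight decay 1e-4, at most 50
    communication rounds, early stopping after 5 rounds without metric
    improvement, base seed 42 and 10 repeats.
    """

    learning_rate: float = 1e-3
    batch_size: int = 32
    local_epochs: int = 1
    max_rounds: int = 50
    early_stop_patience: int = 5
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 42
    repeats: int = 10

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.local_epochs,
               self.max_rounds, self.early_stop_patience) < 0:
            raise ValueError("TrainConfig fields must be nonnegative")
        if self.early_stop_patience > self.max_rounds:
            raise ValueError("patience must not exceed max_rounds")


@dataclass
class Metrics:
    overall_accuracy: float
    overall_f1: float
    per_client: "OrderedDict[str, tuple[float, float]]"
    n_samples: "OrderedDict[str, int]"

    def to_frame(self):
        import pandas as pd
        rows = [{"client_id": cid, "accuracy": acc, "f1": f1,
                 "n_samples": self.n_samples[cid]}
                for cid, (acc, f1) in self.per_client.items()]
        rows.append({"client_id": "overall", "accuracy": self.overall_accuracy,
                     "f1": self.overall_f1, "n_samples": sum(self.n_samples.values())})
        return pd.DataFrame(rows)

    def save(self, path):
        import pandas as pd  # noqa: F401  (to_frame dependency)
        self.to_frame().to_csv(str(path) + ".csv", index=False)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"overall_accuracy": self.overall_accuracy,
                       "overall_f1": self.overall_f1,
                       "per_client": {k: list(v) for k, v in self.per_client.items()},
                       "n_samples": dict(self.n_samples)}, fh, indent=2)


# ------------------------------------------------------------------ operations

def local_train(model_params: ParamVector, data, config: TrainConfig,
                loss_fn: Callable, rng: np.random.Generator | None = None
                ) -> tuple[ParamVector, list[float]]:
    """Generic local SGD pass for a model expressed as a loss over batches.

    `loss_fn(params_dict_of_tensors, batch_indices)` must return a scalar
    autodiff Tensor. Only parameters whose trainable_mask is True are
    updated; frozen entries are returned bit-identical.
    """
    from .nn import SGD, Tensor

    n = len(data)
    if n == 0:
        raise ValueError("empty client dataset")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    tensors = OrderedDict(
        (k, Tensor(v.copy(), requires_grad=model_params.trainable_mask.get(k, True)))
        for k, v in model_params.named_tensors.items())
    trainable = OrderedDict((k, t) for k, t in tensors.items() if t.requires_grad)
    opt = SGD(trainable, lr=config.learning_rate, momentum=config.momentum,
              weight_decay=config.weight_decay)

    trace: list[float] = []
    for _ in range(config.local_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            opt.zero_grad()
            loss = loss_fn(tensors, batch)
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError("NaN/inf loss during local training")
            loss.backward()
            opt.step()
            trace.append(value)

    out = OrderedDict()
    for k, t in tensors.items():
        out[k] = t.data if t.requires_grad else model_params.named_tensors[k]
    return ParamVector(out, dict(model_params.trainable_mask)), trace


def aggregate(params_list: Sequence[ParamVector],
              weights: Sequence[float] | None = None) -> ParamVector:
    """FedAvg: coordinate-wise weighted mean with weights normalized to 1."""
    if len(params_list) == 0:
        raise ValueError("nothing to aggregate")
    ref = params_list[0]
    for p in params_list[1:]:
        if not ref.same_structure(p):
            raise ValueError("ParamVector structure mismatch in aggregation")
    if weights is None:
        weights = np.ones(len(params_list))
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError("aggregation weights must be nonnegative")
    total = w.sum()
    if total == 0:
        raise ValueError("aggregation weights sum to zero")
    w = w / total
    out = OrderedDict()
    for name in ref.names():
        out[name] = sum(wi * p.named_tensors[name] for wi, p in zip(w, params_list))
    return ParamVector(out, dict(ref.trainable_mask))


def run_rounds(clients: Sequence, initial_params: ParamVector, config: TrainConfig,
               local_step: Callable, monitor_metric: Callable | None = None,
               client_weights: Sequence[float] | None = None,
               ) -> tuple[ParamVector, list[dict]]:
    """Synchronous federated rounds with optional early stopping.

    local_step(client, global_params, round_index) -> updated ParamVector.
    monitor_metric(global_params) -> float to maximize; when it fails to
    improve for `early_stop_patience` consecutive rounds the loop stops
    and the best-metric parameters are returned. With no monitor the loop
    runs max_rounds and returns the last aggregate.
    """
    if len(clients) == 0:
        raise ValueError("no clients")
    if client_weights is None:
        client_weights = [len(c) for c in clients]

    global_params = initial_params.copy()
    best_params = global_params
    best_metric = -np.inf
    stall = 0
    history: list[dict] = []

    for rnd in range(1, config.max_rounds + 1):
        local_params = [local_step(client, global_params, rnd) for client in clients]
        global_params = aggregate(local_params, client_weights)
        record = {"round": rnd}
        if monitor_metric is not None:
            metric = float(monitor_metric(global_params))
            record["metric"] = metric
            if metric > best_metric:
                best_metric = metric
                best_params = global_params.copy()
                stall = 0
            else:
                stall += 1
            history.append(record)
            if stall >= config.early_stop_patience:
                logger.info("early stop at round %d (best metric %.4f)", rnd, best_metric)
                break
        else:
            best_params = global_params
            history.append(record)
    return best_params, history


def evaluate(predict_fn: Callable, datasets: Sequence) -> Metrics:
    """Pooled and per-client accuracy and positive-class F1.

    predict_fn(dataset) -> integer class predictions for every sample.
    Overall accuracy is the sample-weighted pooled accuracy; overall F1
    is the binary F1 of class 1 pooled over all test samples.
    """
    if len(datasets) == 0:
        raise ValueError("no evaluation datasets")
    per_client: "OrderedDict[str, tuple[float, float]]" = OrderedDict()
    counts: "OrderedDict[str, int]" = OrderedDict()
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for ds in datasets:
        if len(ds) == 0:
            logger.warning("skipping empty client %s in evaluation", ds.client_id)
            continue
        pred = np.asarray(predict_fn(ds))
        true = np.asarray(ds.class_labels)
        acc = float(np.mean(pred == true))
        f1 = float(f1_score(true, pred, pos_label=1, zero_division=0))
        per_client[str(ds.client_id)] = (acc, f1)
        counts[str(ds.client_id)] = len(ds)
        pooled_true.append(true)
        pooled_pred.append(pred)
    if not per_client:
        raise ValueError("all evaluation clients were empty")
    yt = np.concatenate(pooled_true)
    yp = np.concatenate(pooled_pred)
    return Metrics(
        overall_accuracy=float(np.mean(yp == yt)),
        overall_f1=float(f1_score(yt, yp, pos_label=1, zero_division=0)),
        per_client=per_client,
        n_samples=counts,
    )
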
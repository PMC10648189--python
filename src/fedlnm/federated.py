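"""Federated orchestration: FedAvg aggregation and local client updates.

The simulated federation mirrors a two-hospital setting: each client trains
the shared fusion network on its local records, and only *parameters* cross
the client boundary — the server-side aggregation path receives name->array
mappings, never patient records or images. Aggregation is data-size-weighted
federated averaging ``w = sum_k (n_k / n) w_k``; the published formula carries
an extra 1/K factor that double-normalizes and does not preserve parameter
scale even for identical clients, so it is available only behind
``literal_scaling=True`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Mapping, Sequence

import numpy as np

from .cohort import ClientDataset, MODALITIES, encode_features
from .exceptions import AggregationError, ConfigurationError, InputError
from .model import FusionModel, ModelConfig
from .stats import DiagnosticMetrics, build_contingency, compute_metrics, roc_from_scores

__all__ = [
    "ModelParameters", "FederatedConfig", "RoundLog",
    "fedavg", "local_train", "run_federated", "cross_validate_clients",
    "client_arrays", "evaluate_parameters",
]


class ModelParameters(dict):
    """Named numeric arrays closed under scalar multiplication and addition."""

    def __add__(self, other: "ModelParameters") -> "ModelParameters":
        if set(self) != set(other):
            raise AggregationError("parameter name sets differ")
        return ModelParameters({k: self[k] + other[k] for k in self})

    def __mul__(self, scalar: float) -> "ModelParameters":
        return ModelParameters({k: v * scalar for k, v in self.items()})

    __rmul__ = __mul__

    @property
    def n_elements(self) -> int:
        return int(sum(np.asarray(v).size for v in self.values()))


@dataclass(frozen=True)
class FederatedConfig:
    """Federation hyperparameters; ``model`` carries the architecture."""

    n_rounds: int = 20
    local_epochs: int = 1
    batch_size: int = 16
    learning_rate: float = 1e-3
    momentum: float = 0.9             # classical momentum; 0 = plain SGD
    mode: str = "multimodal"          # or "text_only"
    seed: int = 0
    literal_scaling: bool = False     # apply the published extra 1/K factor
    model: ModelConfig | None = None

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.batch_size < 1:
            raise ConfigurationError("n_rounds and batch_size must be >= 1")
        if self.local_epochs < 0:
            raise ConfigurationError("local_epochs must be >= 0")

    def model_config(self, n_features: int) -> ModelConfig:
        base = self.model or ModelConfig()
        return _dc_replace(base, n_features=n_features, mode=self.mode,
                           seed=self.seed)


@dataclass
class RoundLog:
    """One federated round: per-client loss trajectories + post-aggregation metrics."""

    round_index: int
    client_losses: dict[int, list[float]]
    val_auc: float | None = None
    val_accuracy: float | None = None


def fedavg(params_list: Sequence[Mapping[str, np.ndarray]], n_list: Sequence[int],
           literal_scaling: bool = False) -> ModelParameters:
    """Data-size-weighted average of client parameters.

    Weights are ``n_k / n`` and sum to one; with ``literal_scaling`` the result
    is additionally divided by the number of clients (the formula as published,
    kept only for comparison — it shrinks parameters K-fold).
    """
    if len(params_list) == 0:
        raise InputError("fedavg of an empty client list")
    if len(params_list) != len(n_list):
        raise InputError("params_list and n_list lengths differ")
    n_arr = np.asarray(n_list, dtype=float)
    if np.any(n_arr <= 0):
        raise InputError("client sizes must be positive")
    names = set(params_list[0])
    for p in params_list[1:]:
        if set(p) != names:
            raise AggregationError("client parameter name sets differ")
        for k in names:
            if np.shape(p[k]) != np.shape(params_list[0][k]):
                raise AggregationError(f"shape mismatch for parameter {k!r}")
    weights = n_arr / n_arr.sum()
    if literal_scaling:
        weights = weights / len(params_list)
    out = ModelParameters()
    for k in params_list[0]:
        out[k] = sum(w * np.asarray(p[k], dtype=float)
                     for w, p in zip(weights, params_list))
    return out


def client_arrays(client: ClientDataset, split: str = "train",
                  mode: str = "multimodal",
                  modalities: Sequence[str] = MODALITIES) -> dict:
    """Encode one client split as training arrays (features, labels, images, masks)."""
    if split == "train":
        ids = client.train_ids
    elif split == "test":
        ids = client.test_ids
    elif split == "all":
        ids = client.record_ids()
    else:
        raise InputError(f"unknown split {split!r}")
    records = client.subset(ids)
    X = encode_features(records, modalities)
    y = np.array([r.true_lnm for r in records], dtype=int)
    images = masks = None
    if mode == "multimodal":
        imgs, msks = [], []
        for r in records:
            if r.image_id is None or r.image_id not in client.images:
                raise InputError(f"record {r.patient_id} has no attached image")
            im = client.images[r.image_id]
            imgs.append(im.pixels)
            msks.append(im.mask)
        images = np.stack(imgs)[..., None]
        masks = np.stack(msks).astype(int)
    return {"X": X, "y": y, "images": images, "masks": masks,
            "ids": [r.patient_id for r in records]}


def _sgd_epochs(model: FusionModel, data: dict, cfg: FederatedConfig,
                rng: np.random.Generator) -> list[float]:
    """Minibatch SGD over ``local_epochs`` passes; returns per-batch losses."""
    from .nn import sgd_step

    n = data["y"].shape[0]
    losses: list[float] = []
    velocity: dict[str, np.ndarray] = {}  # fresh momentum state per local run
    for _ in range(cfg.local_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs = data["images"][idx] if data["images"] is not None else None
            msks = data["masks"][idx] if data["masks"] is not None else None
            loss = model.loss_and_backward(data["X"][idx], data["y"][idx],
                                           images=imgs, masks=msks)
            sgd_step(model.parameter_arrays(), model.gradient_arrays(),
                     cfg.learning_rate, momentum=cfg.momentum, velocity=velocity)
            losses.append(loss)
    return losses


def local_train(client: ClientDataset, start: Mapping[str, np.ndarray],
                cfg: FederatedConfig, round_index: int = 0,
                model: FusionModel | None = None
                ) -> tuple[ModelParameters, list[float]]:
    """One client's local refinement from the broadcast parameters.

    Only parameters and losses leave this function — the privacy contract of
    the federation. Deterministic given (cfg.seed, round_index, client_id).
    """
    if len(client.train_ids) == 0:
        raise InputError(f"client {client.client_id} has an empty training split")
    data = client_arrays(client, "train", cfg.mode)
    if model is None:
        model = FusionModel(cfg.model_config(n_features=data["X"].shape[1]))
    model.set_parameters(dict(start))
    rng = np.random.default_rng([cfg.seed, 1000 + round_index, client.client_id])
    losses = _sgd_epochs(model, data, cfg, rng)
    return ModelParameters(model.get_parameters()), losses


def evaluate_parameters(params: Mapping[str, np.ndarray], client: ClientDataset,
                        cfg: FederatedConfig, split: str = "test",
                        model: FusionModel | None = None
                        ) -> tuple[np.ndarray, np.ndarray, DiagnosticMetrics, float | None]:
    """Score one client split with the given parameters.

    Returns (p_positive scores, labels, thresholded DiagnosticMetrics,
    score-based ROC AUC)."""
    data = client_arrays(client, split, cfg.mode)
    if model is None:
        model = FusionModel(cfg.model_config(n_features=data["X"].shape[1]))
    model.set_parameters(dict(params))
    probs = model.predict_proba(data["X"], data["images"])
    scores = probs[:, 1]
    calls = scores >= 0.5
    metrics = compute_metrics(build_contingency(calls, data["y"]))
    _, auc = roc_from_scores(scores, data["y"])
    return scores, data["y"], metrics, auc


def run_federated(clients: Sequence[ClientDataset], cfg: FederatedConfig
                  ) -> tuple[ModelParameters, list[RoundLog]]:
    """Broadcast -> local train -> aggregate, for ``cfg.n_rounds`` rounds.

    Thin wrapper over :class:`fedlnm.estimators.FederatedFusionClassifier`.
    """
    from .estimators import FederatedFusionClassifier

    est = FederatedFusionClassifier.from_config(cfg)
    est.fit_clients(list(clients))
    return est.global_params_, est.round_logs_


def cross_validate_clients(clients: Sequence[ClientDataset],
                           params: Mapping[str, np.ndarray],
                           cfg: FederatedConfig) -> dict[str, dict]:
    """Evaluate the global model on each client's full data as the other's
    validation set (client 0 is validated on client 1's records and vice versa)."""
    if len(clients) != 2:
        raise InputError("cross-validation is defined for exactly two clients")
    out = {}
    for me, other in ((clients[0], clients[1]), (clients[1], clients[0])):
        scores, y, metrics, auc = evaluate_parameters(params, other, cfg, split="all")
        out[f"client{me.client_id}"] = {
            "validation_n": other.n, "metrics": metrics, "auc_scores": auc,
            "scores": scores, "labels": y,
        }
    return out
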
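"""Scikit-learn style estimators over the fusion network.

These classes are the package's primary modeling surface: they follow the
sklearn contract (constructor stores hyperparameters, ``fit`` validates and
learns, fitted attributes end in an underscore, ``get_params``/``set_params``
come from :class:`~sklearn.base.BaseEstimator`), so they compose with
sklearn model selection. The federated estimator trains one shared model with
FedAvg over per-client datasets; only parameter arrays cross the aggregation
boundary.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import ClientDataset
from .exceptions import InputError
from .federated import (FederatedConfig, ModelParameters, _sgd_epochs, client_arrays,
                        fedavg, local_train, RoundLog)
from .model import FusionModel, ModelConfig
from .stats import roc_from_scores

__all__ = ["TextMLPClassifier", "FusionClassifier", "FederatedFusionClassifier"]


class _FusionBase(ClassifierMixin, BaseEstimator):
    """Shared plumbing: model construction and prediction."""

    def _model_config(self, n_features: int, mode: str) -> ModelConfig:
        return ModelConfig(
            n_features=n_features,
            mlp_hidden=tuple(self.mlp_hidden),
            image_size=self.image_size,
            unet_base_channels=self.unet_base_channels,
            unet_depth=self.unet_depth,
            lambda_pixel=self.lambda_pixel,
            mode=mode,
            dtype=self.dtype,
            seed=self.random_state,
        )

    def predict_proba(self, X, images=None) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        return self.model_.predict_proba(X, images)

    def predict(self, X, images=None) -> np.ndarray:
        return self.classes_[(self.predict_proba(X, images)[:, 1] >= 0.5).astype(int)]

    def decision_function(self, X, images=None) -> np.ndarray:
        return self.predict_proba(X, images)[:, 1]


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InputError(f"X {X.shape} and y {y.shape} are not aligned 2-D/1-D arrays")
    classes = np.unique(y)
    y_idx = (y == classes[-1]).astype(int) if classes.size == 2 else y.astype(int)
    return X, y_idx, classes


class TextMLPClassifier(_FusionBase):
    """MLP over encoded clinical/reader features (the text branch alone)."""

    def __init__(self, mlp_hidden=(32, 32), epochs=20, batch_size=16,
                 learning_rate=1e-3, momentum=0.9, random_state=0, dtype="float32",
                 image_size=64, unet_base_channels=4, unet_depth=3,
                 lambda_pixel=0.5):
        self.mlp_hidden = mlp_hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.random_state = random_state
        self.dtype = dtype
        self.image_size = image_size
        self.unet_base_channels = unet_base_channels
        self.unet_depth = unet_depth
        self.lambda_pixel = lambda_pixel

    def fit(self, X, y):
        X, y_idx, self.classes_ = _check_Xy(X, y)
        self.n_features_in_ = X.shape[1]
        cfg = FederatedConfig(local_epochs=self.epochs, batch_size=self.batch_size,
                              learning_rate=self.learning_rate, momentum=self.momentum,
                              mode="text_only", seed=self.random_state)
        self.model_ = FusionModel(self._model_config(X.shape[1], "text_only"))
        data = {"X": X, "y": y_idx, "images": None, "masks": None}
        rng = np.random.default_rng([self.random_state, 500])
        self.loss_curve_ = _sgd_epochs(self.model_, data, cfg, rng)
        return self


class FusionClassifier(_FusionBase):
    """Centralized multimodal classifier: text branch + image branch + fusion."""

    def __init__(self, mlp_hidden=(32, 32), epochs=20, batch_size=16,
                 learning_rate=1e-3, momentum=0.9, lambda_pixel=0.5, image_size=64,
                 unet_base_channels=4, unet_depth=3, random_state=0,
                 dtype="float32"):
        self.mlp_hidden = mlp_hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.lambda_pixel = lambda_pixel
        self.image_size = image_size
        self.unet_base_channels = unet_base_channels
        self.unet_depth = unet_depth
        self.random_state = random_state
        self.dtype = dtype

    def fit(self, X, y, images=None, masks=None):
        X, y_idx, self.classes_ = _check_Xy(X, y)
        self.n_features_in_ = X.shape[1]
        mode = "multimodal" if images is not None else "text_only"
        cfg = FederatedConfig(local_epochs=self.epochs, batch_size=self.batch_size,
                              learning_rate=self.learning_rate, momentum=self.momentum,
                              mode=mode, seed=self.random_state)
        self.model_ = FusionModel(self._model_config(X.shape[1], mode))
        if images is not None:
            images = np.asarray(images, dtype=float)
            if images.ndim == 3:
                images = images[..., None]
        data = {"X": X, "y": y_idx,
                "images": images,
                "masks": np.asarray(masks).astype(int) if masks is not None else None}
        rng = np.random.default_rng([self.random_state, 500])
        self.loss_curve_ = _sgd_epochs(self.model_, data, cfg, rng)
        return self


class FederatedFusionClassifier(_FusionBase):
    """FedAvg-trained fusion model over two (or more) client datasets.

    ``fit_clients`` consumes :class:`~fedlnm.cohort.ClientDataset` objects with
    train/test splits already assigned; each round broadcasts the global
    parameters, refines them locally on every client, and aggregates with
    data-size-weighted FedAvg (weights from training-split sizes). Fitted
    attributes: ``global_params_``, ``round_logs_``, ``model_``.
    """

    def __init__(self, n_rounds=20, local_epochs=1, batch_size=16,
                 learning_rate=1e-3, momentum=0.9, mode="multimodal", lambda_pixel=0.5,
                 mlp_hidden=(32, 32), image_size=64, unet_base_channels=4,
                 unet_depth=3, random_state=0, dtype="float32",
                 literal_scaling=False, track_validation=True):
        self.n_rounds = n_rounds
        self.local_epochs = local_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.mode = mode
        self.lambda_pixel = lambda_pixel
        self.mlp_hidden = mlp_hidden
        self.image_size = image_size
        self.unet_base_channels = unet_base_channels
        self.unet_depth = unet_depth
        self.random_state = random_state
        self.dtype = dtype
        self.literal_scaling = literal_scaling
        self.track_validation = track_validation

    @classmethod
    def from_config(cls, cfg: FederatedConfig) -> "FederatedFusionClassifier":
        model = cfg.model or ModelConfig()
        return cls(n_rounds=cfg.n_rounds, local_epochs=cfg.local_epochs,
                   batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
                   momentum=cfg.momentum, mode=cfg.mode, lambda_pixel=model.lambda_pixel,
                   mlp_hidden=model.mlp_hidden, image_size=model.image_size,
                   unet_base_channels=model.unet_base_channels,
                   unet_depth=model.unet_depth, random_state=cfg.seed,
                   dtype=model.dtype, literal_scaling=cfg.literal_scaling)

    def _fed_config(self, n_features: int) -> FederatedConfig:
        return FederatedConfig(
            n_rounds=self.n_rounds, local_epochs=self.local_epochs,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            momentum=self.momentum, mode=self.mode, seed=self.random_state,
            literal_scaling=self.literal_scaling,
            model=self._model_config(n_features, self.mode))

    def fit_clients(self, clients: list[ClientDataset]):
        if not clients:
            raise InputError("need at least one client")
        n_features = client_arrays(clients[0], "train", "text_only")["X"].shape[1]
        cfg = self._fed_config(n_features)
        self.config_ = cfg
        self.model_ = FusionModel(cfg.model_config(n_features))
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = n_features
        global_params = ModelParameters(self.model_.get_parameters())
        sizes = [len(c.train_ids) for c in clients]

        # held-out pool for per-round validation metrics
        test_data = None
        if self.track_validation:
            parts = [client_arrays(c, "test", self.mode) for c in clients
                     if len(c.test_ids)]
            if parts:
                test_data = {
                    "X": np.concatenate([p["X"] for p in parts]),
                    "y": np.concatenate([p["y"] for p in parts]),
                    "images": (np.concatenate([p["images"] for p in parts])
                               if parts[0]["images"] is not None else None),
                }

        self.round_logs_ = []
        for r in range(cfg.n_rounds):
            # broadcast + local refinement; only parameters come back
            results = [local_train(c, global_params, cfg, round_index=r,
                                   model=self.model_) for c in clients]
            global_params = fedavg([p for p, _ in results], sizes,
                                   literal_scaling=self.literal_scaling)
            log = RoundLog(round_index=r,
                           client_losses={c.client_id: losses
                                          for c, (_, losses) in zip(clients, results)})
            if test_data is not None:
                self.model_.set_parameters(dict(global_params))
                probs = self.model_.predict_proba(test_data["X"], test_data["images"])
                _, auc = roc_from_scores(probs[:, 1], test_data["y"])
                log.val_auc = auc
                log.val_accuracy = float(np.mean((probs[:, 1] >= 0.5) == test_data["y"]))
            self.round_logs_.append(log)

        self.global_params_ = global_params
        self.model_.set_parameters(dict(global_params))
        return self

    def fit(self, X, y, groups=None, images=None, masks=None):
        """Array-based federation: rows are assigned to clients by ``groups``.

        Provided for sklearn-style use on pre-encoded arrays; ``fit_clients``
        is the primary entry point for cohort objects.
        """
        X, y_idx, self.classes_ = _check_Xy(X, y)
        groups = np.zeros(len(y_idx), dtype=int) if groups is None else np.asarray(groups)
        if images is not None:
            images = np.asarray(images, dtype=float)
            if images.ndim == 3:
                images = images[..., None]
        masks = np.asarray(masks).astype(int) if masks is not None else None

        cfg = self._fed_config(X.shape[1])
        self.config_ = cfg
        self.n_features_in_ = X.shape[1]
        self.model_ = FusionModel(cfg.model_config(X.shape[1]))
        global_params = ModelParameters(self.model_.get_parameters())
        uniq = np.unique(groups)
        bundles = []
        for g in uniq:
            sel = groups == g
            bundles.append({"X": X[sel], "y": y_idx[sel],
                            "images": images[sel] if images is not None else None,
                            "masks": masks[sel] if masks is not None else None})
        sizes = [b["y"].shape[0] for b in bundles]
        self.round_logs_ = []
        for r in range(cfg.n_rounds):
            params_list, losses_all = [], {}
            for gi, b in enumerate(bundles):
                self.model_.set_parameters(dict(global_params))
                rng = np.random.default_rng([cfg.seed, 1000 + r, int(uniq[gi])])
                losses_all[int(uniq[gi])] = _sgd_epochs(self.model_, b, cfg, rng)
                params_list.append(ModelParameters(self.model_.get_parameters()))
            global_params = fedavg(params_list, sizes,
                                   literal_scaling=self.literal_scaling)
            self.round_logs_.append(RoundLog(round_index=r, client_losses=losses_all))
        self.global_params_ = global_params
        self.model_.set_parameters(dict(global_params))
        return self
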
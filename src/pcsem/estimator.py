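"""Scikit-learn style front end for the attention-augmented tool classifier."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .metrics import mean_average_precision
from .resnet import ModelSpec, build_model
from .training import TrainConfig, evaluate, predict_scores, train


class ToolPresenceClassifier(BaseEstimator):
    """Multi-label tool-presence classifier: ResNet50 + optional attention.

    Follows the scikit-learn estimator protocol: hyper-parameters are
    constructor arguments, :meth:`fit` trains and sets trailing-underscore
    attributes, and the object composes with ``clone``/``get_params``.

    Parameters
    ----------
    attention : {None, "se", "cbam", "pcsem"}
        Attention block injected into the backbone (None = plain ResNet50).
    place : {1, 2, 3}
        Placement scheme; 2 (after conv blocks 2-4, 3 blocks) is the
        recommended default.
    reduction : int
        Channel-bottleneck divisor R of the attention MLPs.
    head_classes : int
        Output units (7 tools by default; 8 adds a no-tool unit).
    epochs, batch_size, lr0, lr_decay, momentum
        Training recipe (defaults are the reference settings).
    seed : int
        Controls weight init and batch order; same seed, same fit.

    Attributes
    ----------
    model_ : the trained network.
    log_ : the per-iteration training log.
    n_features_in_ : flattened input size seen during fit.
    """

    def __init__(self, attention: str | None = "pcsem", place: int = 2,
                 reduction: int = 16, head_classes: int = 7, epochs: int = 10,
                 batch_size: int = 50, lr0: float = 0.002,
                 lr_decay: float = 0.0009, momentum: float = 0.9, seed: int = 0):
        self.attention = attention
        self.place = place
        self.reduction = reduction
        self.head_classes = head_classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.momentum = momentum
        self.seed = seed

    # -- estimator protocol -------------------------------------------------
    def _spec(self) -> ModelSpec:
        placement = "none" if self.attention is None else f"place{self.place}"
        return ModelSpec(attention=self.attention, placement=placement,
                         reduction=self.reduction, head_classes=self.head_classes)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(lr0=self.lr0, lr_decay=self.lr_decay,
                           epochs=self.epochs, batch_size=self.batch_size,
                           momentum=self.momentum, seed=self.seed)

    @staticmethod
    def _check_x(x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("X must be an (N, 3, H, W) image stack")
        return x

    def fit(self, X, y):
        x = self._check_x(X)
        y = np.asarray(y, dtype=np.float32)
        if y.ndim != 2 or len(y) != len(x):
            raise ValueError("y must be (N, n_classes) multi-label flags")
        self.model_ = build_model(self._spec(), seed=self.seed)
        self.model_, self.log_ = train(self.model_, (x, y), self._train_config())
        self.n_features_in_ = int(np.prod(x.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._require_fitted()
        return predict_scores(self.model_, self._check_x(X), self.batch_size)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.int8)

    def score(self, X, y) -> float:
        """Mean average precision over classes with positive labels."""
        self._require_fitted()
        scores = self.predict_proba(X)
        return mean_average_precision(scores, np.asarray(y, dtype=int)).map

    def evaluate(self, X, y, thresholds=None):
        self._require_fitted()
        x = self._check_x(X)
        return evaluate(self.model_, (x, np.asarray(y, dtype=np.float32)),
                        thresholds, self.batch_size)

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this ToolPresenceClassifier instance is not "
                               "fitted yet; call fit first")
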
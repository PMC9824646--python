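"""Scikit-learn-style estimator wrapping the full pipeline.

``CSBNetClassifier`` composes with sklearn model selection and pipelines:
``fit(X, y)`` trains the network on normalized (N, 3, 224, 224) image
arrays, ``predict``/``predict_proba`` classify, and fitted state lives in
trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .config import ModelConfig, TrainConfig
from .model import count_params
from .preprocessing import ImageBatch
from .training import softmax, train_model


class CSBNetClassifier(BaseEstimator, ClassifierMixin):
    """Compressed-domain image classifier with a learned measurement block.

    Parameters
    ----------
    sr : sensing rate in (0, 1]; the measurement map carries
        X = round(192 * sr) channels.
    attention : "se", "eca", "cbam" or "none".
    feat_widths : output widths of feature convolutions 2-5.
    epochs, batch_size, learning_rate : Adam training-loop settings.
    augment : apply seeded flips/brightness jitter to training batches.
    random_state : master seed for init, shuffling, dropout, augmentation.

    Attributes
    ----------
    classes_ : array of class labels seen in fit.
    network_ : the trained :class:`~csbnet.model.Network`.
    history_ : per-epoch :class:`~csbnet.training.History`.
    n_parameters_ : total trainable-parameter count.
    """

    def __init__(
        self,
        sr: float = 0.7,
        attention: str = "se",
        feat_widths: tuple[int, int, int, int] = (408, 344, 286, 128),
        se_reduction: int = 16,
        dropout_p: float = 0.5,
        epochs: int = 5,
        batch_size: int = 8,
        learning_rate: float = 1e-4,
        augment: bool = True,
        random_state: int = 0,
    ) -> None:
        self.sr = sr
        self.attention = attention
        self.feat_widths = feat_widths
        self.se_reduction = se_reduction
        self.dropout_p = dropout_p
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.augment = augment
        self.random_state = random_state

    def _validate_images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1:] != (3, 224, 224):
            raise ValueError(f"X must have shape (N, 3, 224, 224), got {X.shape}")
        return X

    def _model_config(self, num_classes: int) -> ModelConfig:
        return ModelConfig(
            sr=self.sr,
            num_classes=num_classes,
            feat_widths=tuple(self.feat_widths),
            attention=self.attention,
            se_reduction=self.se_reduction,
            dropout_p=self.dropout_p,
            fc_dims=(self.feat_widths[3] * 4, 1024, 2048),
        )

    def fit(self, X: np.ndarray, y: np.ndarray, X_val=None, y_val=None) -> "CSBNetClassifier":
        X = self._validate_images(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths disagree")
        self.classes_, encoded = np.unique(y, return_inverse=True)
        names = [str(c) for c in self.classes_]
        train_batch = ImageBatch(X, encoded, names)
        if X_val is not None:
            Xv = self._validate_images(X_val)
            yv = np.searchsorted(self.classes_, np.asarray(y_val))
            val_batch = ImageBatch(Xv, yv, names)
        else:
            val_batch = ImageBatch(
                np.empty((0, 3, 224, 224), np.float32), np.empty(0, np.int64), names
            )
        config = self._model_config(len(self.classes_))
        tc = TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
            augment=self.augment,
        )
        self.network_, self.history_ = train_model(config, train_batch, val_batch, tc)
        self.config_ = config
        self.ledger_ = count_params(self.network_)
        self.n_parameters_ = self.ledger_.total
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "network_")
        return self.network_.predict_scores(self._validate_images(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[scores.argmax(axis=1)]
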
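"""scikit-learn style estimator facade.

:class:`StrokeSegmenter` wraps variant selection, weight initialisation,
training and inference behind the familiar ``fit`` / ``predict`` /
``predict_proba`` surface, so the segmenter composes with sklearn pipelines,
``clone`` and parameter search.  ``X`` is an array of slices ``(n, H, W)``
in [0, 1], ``y`` the matching binary masks.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
from sklearn.base import BaseEstimator

from .model import (ModelConfig, binarize, build_model, count_parameters)
from .train import evaluate_model, train_model

__all__ = ["StrokeSegmenter"]


class StrokeSegmenter(BaseEstimator):
    """Transformer-augmented dilated dense U-Net segmenter.

    Parameters mirror the run configuration; ``None`` width overrides fall
    back to the calibrated defaults.  Fitted attributes: ``model_`` (the
    network), ``history_`` (per-epoch logs), ``param_count_``.
    """

    def __init__(self, variant: str = "transformer_dil_denseunet",
                 loss: str = "bce_dice", learning_rate: float = 1e-4,
                 batch_size: int = 8, epochs: int = 100,
                 dropout: float = 0.2, threshold: float = 0.5,
                 stem_width: int | None = None,
                 dilated_channels: int | None = None,
                 growth: int | None = None,
                 dense_layers: int | None = None,
                 embed_dim: int | None = None,
                 ffn_dim: int | None = None,
                 heads: int | None = None,
                 random_state: int = 0):
        self.variant = variant
        self.loss = loss
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout = dropout
        self.threshold = threshold
        self.stem_width = stem_width
        self.dilated_channels = dilated_channels
        self.growth = growth
        self.dense_layers = dense_layers
        self.embed_dim = embed_dim
        self.ffn_dim = ffn_dim
        self.heads = heads
        self.random_state = random_state

    # -- sklearn API -------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        overrides = {"variant": self.variant, "dropout": self.dropout}
        for name in ("stem_width", "dilated_channels", "growth",
                     "dense_layers", "embed_dim", "ffn_dim", "heads"):
            value = getattr(self, name)
            if value is not None:
                overrides[name] = value
        return ModelConfig(**{**asdict(ModelConfig()), **overrides})

    def fit(self, X, y, **fit_params) -> "StrokeSegmenter":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError("X must be (n, H, W) slices with masks y of "
                             "the same shape")
        self.model_ = build_model(self._model_config(),
                                  seed=self.random_state)
        self.history_ = train_model(
            self.model_, X, y, loss=self.loss,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, seed=self.random_state, **fit_params)
        self.param_count_ = count_parameters(self.model_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self.model_.predict(np.asarray(X, dtype=np.float32))

    def predict(self, X) -> np.ndarray:
        return binarize(self.predict_proba(X), self.threshold)

    def score(self, X, y) -> float:
        """Mean Dice coefficient over the given slices."""
        self._check_fitted()
        report = evaluate_model(self.model_, np.asarray(X, np.float32),
                                np.asarray(y), self.threshold)
        return report["mean_dice"]

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this StrokeSegmenter is not fitted yet")
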
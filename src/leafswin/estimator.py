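"""Scikit-learn estimator wrapper around the dual-channel transformer.

:class:`DualSwinClassifier` follows the estimator contract — ``fit`` /
``predict`` / ``predict_proba``, ``get_params`` / ``set_params``, fitted
attributes with a trailing underscore — so it composes with sklearn model
selection and pipelines.  Inputs are image stacks ``(n, H, W, 3)`` in [0, 1].
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .augment import AugPolicy
from .model import DualSwinTransformer
from .swin import ModelConfig
from .training import TrainConfig, train

__all__ = ["DualSwinClassifier"]


class DualSwinClassifier(BaseEstimator, ClassifierMixin):
    """Two-channel shifted-window transformer classifier.

    Parameters mirror the architecture and training protocol; defaults are
    the full-size configuration (224 px, C=96, depths 2/2/6/2, batch 8, Adam
    at 1e-4 for 100 epochs).  Desk-scale experiments shrink ``image_size``,
    ``embed_dim``, ``depths`` and ``epochs``.

    Examples
    --------
    >>> clf = DualSwinClassifier(image_size=56, embed_dim=32, depths=(2, 2),
    ...                          num_heads=(2, 4), epochs=5, learning_rate=1e-3)
    >>> clf.fit(X, y).predict_proba(X).shape      # doctest: +SKIP
    (n, n_classes)
    """

    def __init__(self, image_size: int = 224, patch_size: int = 4, embed_dim: int = 96,
                 depths: tuple[int, ...] = (2, 2, 6, 2),
                 num_heads: tuple[int, ...] = (3, 6, 12, 24), window_size: int = 7,
                 mlp_ratio: float = 4.0, drop_path_rate: float = 0.0,
                 rel_pos_bias: bool = True, trainable_sobel: bool = True,
                 epochs: int = 100, batch_size: int = 8, learning_rate: float = 1e-4,
                 weight_decay: float = 0.0, augment: AugPolicy | None = None,
                 seed: int = 0):
        self.image_size = image_size
        self.patch_size = patch_size
        self.embed_dim = embed_dim
        self.depths = depths
        self.num_heads = num_heads
        self.window_size = window_size
        self.mlp_ratio = mlp_ratio
        self.drop_path_rate = drop_path_rate
        self.rel_pos_bias = rel_pos_bias
        self.trainable_sobel = trainable_sobel
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.augment = augment
        self.seed = seed

    # -- estimator API -----------------------------------------------------

    def _model_config(self, n_classes: int) -> ModelConfig:
        return ModelConfig(
            image_size=self.image_size, patch_size=self.patch_size,
            embed_dim=self.embed_dim, window_size=self.window_size,
            depths=tuple(self.depths), num_heads=tuple(self.num_heads),
            num_classes=n_classes, mlp_ratio=self.mlp_ratio,
            drop_path_rate=self.drop_path_rate, rel_pos_bias=self.rel_pos_bias)

    def _validate_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must have shape (n, H, W, 3); got {X.shape}")
        if X.shape[1] != self.image_size or X.shape[2] != self.image_size:
            raise ValueError(
                f"images are {X.shape[1]}x{X.shape[2]} but the estimator expects "
                f"{self.image_size}x{self.image_size}")
        if not np.all(np.isfinite(X)):
            raise ValueError("images must be finite")
        return X

    def fit(self, X, y, X_val=None, y_val=None) -> "DualSwinClassifier":
        X = self._validate_images(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y disagree in length")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.model_ = DualSwinTransformer(
            self._model_config(len(self.classes_)), seed=self.seed,
            trainable_sobel=self.trainable_sobel)
        config = TrainConfig(
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            epochs=self.epochs, seed=self.seed, weight_decay=self.weight_decay,
            augment=self.augment)
        val = None
        if X_val is not None:
            val = (self._validate_images(X_val),
                   np.searchsorted(self.classes_, np.asarray(y_val)))
        result = train(self.model_, (X, y_enc), config, val_data=val)
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        if result.best_state is not None:
            self.model_.load_state_dict(result.best_state)
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this DualSwinClassifier instance is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate_images(X)
        out = []
        for start in range(0, X.shape[0], self.batch_size):
            out.append(self.model_.predict(X[start:start + self.batch_size]).probabilities)
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=-1)]

    def transform(self, X) -> np.ndarray:
        """Fused pre-head feature vectors, shape ``(n, 2 * 8C)``."""
        self._check_fitted()
        X = self._validate_images(X)
        out = []
        for start in range(0, X.shape[0], self.batch_size):
            out.append(self.model_.predict(X[start:start + self.batch_size]).features)
        return np.concatenate(out, axis=0)
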
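"""Scikit-learn style estimators wrapping the segmentation workflow.

:class:`MulticlassSegmenter` learns the global multi-region segmentation
from labelled 48×48 tiles; :class:`BinaryRegionSegmenter` is seeded from
a fitted multi-class model and fine-tuned on click patches for one region.
Both follow the sklearn estimator contract (``get_params``/``set_params``,
fitted attributes with a trailing underscore) and compose with
``sklearn.base.clone``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import ModelConfig, reference_config
from .inference import segment_image
from .model import build_model, count_trainable_parameters
from .training import (
    ClickSet,
    TrainConfig,
    finetune_binary,
    fit_tiles,
    init_binary_from_multiclass,
)

__all__ = ["MulticlassSegmenter", "BinaryRegionSegmenter"]


def _check_tiles(X: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    S = cfg.input_size
    if X.ndim != 4 or X.shape[1] != cfg.in_channels or X.shape[2:] != (S, S):
        raise ValueError(
            f"X must have shape (n_tiles, {cfg.in_channels}, {S}, {S}), got {X.shape}"
        )
    return X


class MulticlassSegmenter(BaseEstimator):
    """Multi-class tile segmenter built on the shifted-window network.

    Parameters
    ----------
    config : ModelConfig or None
        Network architecture; ``None`` selects the frozen reference
        configuration with ``num_classes`` output classes.
    num_classes : int
        Output classes (regions + background), used when ``config`` is None.
    epochs, lr, batch_size, weight_decay : optimisation settings.
    seed : int
        Seeds both parameter initialisation and the shuffling generator.
    """

    def __init__(
        self,
        config: ModelConfig | None = None,
        num_classes: int = 11,
        epochs: int = 100,
        lr: float = 1e-4,
        batch_size: int = 32,
        weight_decay: float = 0.0,
        seed: int = 0,
    ):
        self.config = config
        self.num_classes = num_classes
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.seed = seed

    def _resolved_config(self) -> ModelConfig:
        return self.config if self.config is not None else reference_config(self.num_classes)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MulticlassSegmenter":
        """Fit on tiles X (n, C, S, S) with per-pixel labels y (n, S, S)."""
        cfg = self._resolved_config()
        X = _check_tiles(X, cfg)
        y = np.asarray(y, dtype=np.int64)
        self.model_ = build_model(cfg, seed=self.seed)
        tc = TrainConfig(
            epochs=self.epochs,
            lr=self.lr,
            batch_size=self.batch_size,
            weight_decay=self.weight_decay,
            seed=self.seed,
        )
        self.loss_history_ = fit_tiles(self.model_, X, y, tc)
        self.n_classes_ = cfg.num_classes
        self.n_parameters_ = count_trainable_parameters(self.model_)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Per-pixel label maps (n, S, S) for a stack of tiles."""
        check_is_fitted(self, "model_")
        return self.model_.predict_labels(_check_tiles(X, self.model_.config))

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_logits(_check_tiles(X, self.model_.config))

    def segment(self, image: np.ndarray, f: int = 4) -> np.ndarray:
        """Mode-smoothed whole-image segmentation at stride ``f``."""
        check_is_fitted(self, "model_")
        return segment_image(self.model_, image, f=f)


class BinaryRegionSegmenter(BaseEstimator):
    """Region-vs-background segmenter seeded from a multi-class model.

    ``fit`` consumes click patches: X of shape (n, C, S, S) and y of n
    patch-level labels in {0, 1} (whole patch background / region), the
    label granularity an expert supplies interactively.  Alternatively
    :meth:`fit_clicks` takes a :class:`ClickSet` plus the source image.
    """

    def __init__(
        self,
        base_model=None,
        epochs: int = 100,
        lr: float = 1e-5,
        batch_size: int = 32,
        weight_decay: float = 0.0,
        seed: int = 0,
        head_init: str = "random",
        region_id: int | None = None,
        warm_start: bool = False,
    ):
        self.base_model = base_model
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.seed = seed
        self.head_init = head_init
        self.region_id = region_id
        self.warm_start = warm_start

    def _seed_model(self):
        base = self.base_model
        if base is None:
            raise ValueError("base_model (a fitted multi-class model) is required")
        if isinstance(base, MulticlassSegmenter):
            check_is_fitted(base, "model_")
            base = base.model_
        return init_binary_from_multiclass(
            base, seed=self.seed, head_init=self.head_init, region_id=self.region_id
        )

    def _train_cfg(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            lr=self.lr,
            batch_size=self.batch_size,
            weight_decay=self.weight_decay,
            seed=self.seed,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BinaryRegionSegmenter":
        """Fine-tune on click patches with patch-level binary labels."""
        if not (self.warm_start and hasattr(self, "model_")):
            self.model_ = self._seed_model()
        X = _check_tiles(X, self.model_.config)
        y = np.asarray(y, dtype=np.int64)
        if y.ndim != 1 or set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be patch-level labels in {0, 1}")
        S = self.model_.config.input_size
        tiles_y = np.repeat(y[:, None, None], S, axis=1).repeat(S, axis=2)
        self.loss_history_ = fit_tiles(self.model_, X, tiles_y, self._train_cfg())
        return self

    def fit_clicks(self, clicks: ClickSet, image: np.ndarray) -> "BinaryRegionSegmenter":
        """Fine-tune from a ClickSet against its source image."""
        if not (self.warm_start and hasattr(self, "model_")):
            self.model_ = self._seed_model()
        self.model_, self.loss_history_ = finetune_binary(
            self.model_, clicks, image, self._train_cfg()
        )
        self.clicks_ = clicks
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_labels(_check_tiles(X, self.model_.config))

    def segment(self, image: np.ndarray, f: int = 4) -> np.ndarray:
        check_is_fitted(self, "model_")
        return segment_image(self.model_, image, f=f)
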
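"""Scikit-learn-style estimators over the attention pipeline.

:class:`CNNClassifier` fits one backbone with the weighted focal loss;
:class:`AttentionEnsembleClassifier` runs the full two-stage protocol
(stage-1 crop generation, per-fold bagging of two backbones, convex score
fusion).  Both follow the sklearn contract — ``fit`` / ``predict`` /
``predict_proba``, ``get_params`` / ``set_params``, fitted attributes
with trailing underscores — and compose with sklearn model selection.

``X`` is an ``(n, H, W, 3)`` float image array in [0, 1]; ``y`` is an
``(n, C)`` binary multi-label matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .cropping import attention_box
from .data_io import LabelledDataset, Record
from .ensemble import FusionWeights, predict_ensemble
from .models import build_backbone
from .training import TrainConfig, class_weights_from_frequencies, fit_network, train_two_stage

__all__ = ["CNNClassifier", "AttentionEnsembleClassifier"]


def _check_Xy(X, y=None):
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError(f"X must be (n, H, W, 3) RGB images, got {X.shape}")
    if y is None:
        return X
    y = np.asarray(y)
    if y.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError(f"y must be (n, C) binary labels, got {y.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y entries must be 0/1")
    return X, y


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """Multi-label CNN classifier trained with weighted focal loss.

    Parameters mirror :class:`~fundcam.training.TrainConfig`; the fitted
    network is exposed as ``net_`` and the training curve as ``history_``.
    """

    def __init__(self, backbone: str = "tiny_cnn", epochs: int = 30,
                 batch_size: int = 16, lr_init: float = 1e-4, gamma: float = 2.0,
                 use_class_weights: bool = True, val_fraction: float = 0.2,
                 early_stop_patience: int = 20, seed: int = 0):
        self.backbone = backbone
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_init = lr_init
        self.gamma = gamma
        self.use_class_weights = use_class_weights
        self.val_fraction = val_fraction
        self.early_stop_patience = early_stop_patience
        self.seed = seed

    def _cfg(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           lr_init=self.lr_init, gamma=self.gamma,
                           use_class_weights=self.use_class_weights,
                           val_fraction=self.val_fraction,
                           early_stop_patience=self.early_stop_patience,
                           seed=self.seed)

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        rng = np.random.default_rng(self.seed)
        self.n_classes_ = y.shape[1]
        self.input_size_ = X.shape[1:3]
        self.classes_ = np.arange(self.n_classes_)
        net = build_backbone(self.backbone, self.n_classes_, input_size=self.input_size_,
                             seed=int(rng.integers(2 ** 31)))
        alpha = class_weights_from_frequencies(y) if self.use_class_weights else 1.0
        Xc = np.moveaxis(X, -1, 1)
        self.history_ = fit_network(net, Xc, y.astype(np.float64), self._cfg(), rng,
                                    alpha=alpha)
        self.net_ = net
        return self

    def predict_proba(self, X):
        X = _check_Xy(X)
        return self.net_.predict_proba(np.moveaxis(X, -1, 1))

    def predict(self, X, threshold: float = 0.5):
        return (self.predict_proba(X) >= threshold).astype(np.int64)

    def attention_boxes(self, X, y, theta: float = 128.0, source: str = "gradcam"):
        """Per-sample attention bounding boxes over the true-positive classes."""
        X, y = _check_Xy(X, y)
        boxes = []
        for img, lab in zip(X, y):
            classes = np.flatnonzero(lab).tolist()
            boxes.append(attention_box(self.net_, img, classes, theta=theta,
                                       source=source) if classes else None)
        return boxes


class AttentionEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Two-stage attention-crop training + fold-bagged two-model fusion."""

    def __init__(self, backbones: tuple[str, str] = ("vgg19", "resnet50"),
                 folds: int = 5, epochs: int = 30, batch_size: int = 16,
                 lr_init: float = 1e-4, gamma: float = 2.0, theta: float = 128.0,
                 lam: float = 0.6, sigma: float = 0.4,
                 use_attention_crops: bool = True, use_classic_augment: bool = True,
                 attention_source: str = "gradcam", seed: int = 0):
        self.backbones = backbones
        self.folds = folds
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_init = lr_init
        self.gamma = gamma
        self.theta = theta
        self.lam = lam
        self.sigma = sigma
        self.use_attention_crops = use_attention_crops
        self.use_classic_augment = use_classic_augment
        self.attention_source = attention_source
        self.seed = seed

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        self.n_classes_ = y.shape[1]
        self.input_size_ = X.shape[1:3]
        self.classes_ = np.arange(self.n_classes_)
        dataset = LabelledDataset(
            records=[Record(image_id=f"im_{i:04d}", labels=lab, image=img)
                     for i, (img, lab) in enumerate(zip(X, y))],
            class_names=[f"class_{c}" for c in range(self.n_classes_)])
        cfg = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                          lr_init=self.lr_init, gamma=self.gamma, folds=self.folds,
                          theta=self.theta, attention_source=self.attention_source,
                          use_attention_crops=self.use_attention_crops,
                          use_classic_augment=self.use_classic_augment, seed=self.seed)
        self.checkpoints_, self.train_set_, self.manifest_ = train_two_stage(
            dataset, cfg, backbones=tuple(self.backbones), input_size=self.input_size_)
        return self

    def predict_proba(self, X):
        X = _check_Xy(X)
        return predict_ensemble(self.checkpoints_, np.moveaxis(X, -1, 1),
                                self.n_classes_, self.input_size_,
                                FusionWeights(self.lam, self.sigma))

    def predict(self, X, threshold: float = 0.5):
        return (self.predict_proba(X) >= threshold).astype(np.int64)
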
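"""Score fusion, fold bagging, multi-label metrics and the ablation harness.

Two backbone architectures each contribute the mean prediction of their
cross-validation fold models; the two architecture-level score matrices
``G1, G2`` are then fused convexly,

.. math:: G_f = \\lambda G_1 + \\sigma G_2, \\qquad \\lambda + \\sigma = 1,

with default weights (0.6, 0.4).  Metrics are computed micro-averaged
over all (image, class) cells at a 0.5 decision threshold by default;
per-class ROC AUC uses the rank statistic with ties counted half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from .data_io import LabelledDataset
from .models import build_backbone
from .training import Checkpoint, TrainConfig, train_two_stage

__all__ = [
    "FusionWeights",
    "MetricsReport",
    "fuse_scores",
    "aggregate_folds",
    "multilabel_metrics",
    "roc_auc",
    "predict_ensemble",
    "run_ablation",
]


@dataclass(frozen=True)
class FusionWeights:
    lam: float = 0.6
    sigma: float = 0.4

    def __post_init__(self) -> None:
        if not (0 <= self.lam <= 1 and 0 <= self.sigma <= 1):
            raise ValueError("fusion weights must lie in [0, 1]")
        if abs(self.lam + self.sigma - 1.0) > 1e-9:
            raise ValueError(f"fusion weights must sum to 1, got {self.lam + self.sigma}")


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class_auc: list[float | None]
    mean_auc: float | None
    averaging_mode: str = "micro"
    n_undefined_auc: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "per_class_auc": self.per_class_auc, "mean_auc": self.mean_auc,
            "averaging_mode": self.averaging_mode,
            "n_undefined_auc": self.n_undefined_auc, **self.extras,
        }


def fuse_scores(g1: np.ndarray, g2: np.ndarray,
                weights: FusionWeights | tuple[float, float] = FusionWeights()) -> np.ndarray:
    """Convex combination of two score matrices."""
    if not isinstance(weights, FusionWeights):
        weights = FusionWeights(*weights)
    g1, g2 = np.asarray(g1, dtype=np.float64), np.asarray(g2, dtype=np.float64)
    if g1.shape != g2.shape:
        raise ValueError(f"score shapes differ: {g1.shape} vs {g2.shape}")
    return weights.lam * g1 + weights.sigma * g2


def aggregate_folds(fold_scores: list[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of one architecture's fold predictions."""
    if not fold_scores:
        raise ValueError("need at least one fold score matrix")
    stack = np.stack([np.asarray(s, dtype=np.float64) for s in fold_scores])
    if stack.ndim != 3:
        raise ValueError("fold score matrices must share one shape")
    return stack.mean(axis=0)


def multilabel_metrics(scores: np.ndarray, labels: np.ndarray,
                       decision_threshold: float = 0.5,
                       averaging_mode: str = "micro") -> MetricsReport:
    """Binarize scores at the threshold and report accuracy/P/R/F1 + AUC."""
    if not 0 < decision_threshold < 1:
        raise ValueError("decision threshold must be in (0, 1)")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(f"shape mismatch {scores.shape} vs {labels.shape}")
    pred = (scores >= decision_threshold).astype(np.int64)
    average = {"micro": "micro", "macro": "macro"}[averaging_mode]
    prec, rec, f1, _ = precision_recall_fscore_support(
        labels.ravel() if average == "micro" else labels,
        pred.ravel() if average == "micro" else pred,
        average="binary" if average == "micro" else "macro",
        zero_division=0)
    accuracy = float((pred == labels).mean())  # micro cell accuracy
    aucs: list[float | None] = []
    for c in range(labels.shape[1]):
        aucs.append(roc_auc(scores[:, c], labels[:, c]))
    defined = [a for a in aucs if a is not None]
    mean_auc = float(np.mean(defined)) if defined else None
    return MetricsReport(accuracy=accuracy, precision=float(prec), recall=float(rec),
                         f1=float(f1), per_class_auc=aucs, mean_auc=mean_auc,
                         averaging_mode=averaging_mode,
                         n_undefined_auc=len(aucs) - len(defined))


def roc_auc(scores_c: np.ndarray, labels_c: np.ndarray) -> float | None:
    """Per-class ROC AUC; ``None`` when only one class is present."""
    labels_c = np.asarray(labels_c)
    if labels_c.min() == labels_c.max():
        return None
    return float(roc_auc_score(labels_c, np.asarray(scores_c, dtype=np.float64)))


def predict_ensemble(checkpoints: list[Checkpoint], X: np.ndarray, n_classes: int,
                     input_size: tuple[int, int],
                     weights: FusionWeights = FusionWeights()) -> np.ndarray:
    """Bag fold models within each architecture, then fuse across them.

    With a single architecture the fold mean is returned unfused.
    """
    by_arch: dict[str, list[np.ndarray]] = {}
    for ckpt in checkpoints:
        net = build_backbone(ckpt.backbone, n_classes, input_size=input_size)
        net.load_state_dict(ckpt.state)
        by_arch.setdefault(ckpt.backbone, []).append(net.predict_proba(X))
    arch_scores = [aggregate_folds(v) for v in by_arch.values()]
    if len(arch_scores) == 1:
        return arch_scores[0]
    if len(arch_scores) != 2:
        raise ValueError("score fusion is defined for one or two architectures")
    return fuse_scores(arch_scores[0], arch_scores[1], weights)


def run_ablation(train_set: LabelledDataset, test_set: LabelledDataset,
                 cfg: TrainConfig, backbones: tuple[str, str] = ("vgg19", "resnet50"),
                 weights: FusionWeights = FusionWeights(),
                 decision_threshold: float = 0.5) -> list[dict]:
    """Four-row module-comparison report.

    Rows: each backbone alone (fold-bagged), their fused ensemble, and the
    fused ensemble retrained with attention-crop enlargement.  The first
    three rows share one training run without attention crops, so the
    ensemble row is an exact fusion of the single-model rows.
    """
    size = train_set.get_image(0).shape[:2]
    C = train_set.n_classes
    X_test = np.stack([np.moveaxis(test_set.get_image(i), -1, 0)
                       for i in range(len(test_set))])
    y_test = test_set.label_matrix()

    from dataclasses import replace
    base_cfg = replace(cfg, use_attention_crops=False)
    ckpts_plain, _, _ = train_two_stage(train_set, base_cfg, backbones=backbones,
                                        input_size=size)
    per_arch = {}
    for name in backbones:
        folds = [c for c in ckpts_plain if c.backbone == name]
        per_arch[name] = predict_ensemble(folds, X_test, C, size, weights)

    rows: list[dict] = []
    for name in backbones:
        rep = multilabel_metrics(per_arch[name], y_test, decision_threshold)
        rows.append({"row": name, **rep.to_dict()})
    fused = fuse_scores(per_arch[backbones[0]], per_arch[backbones[1]], weights)
    rep = multilabel_metrics(fused, y_test, decision_threshold)
    rows.append({"row": "ensemble", **rep.to_dict()})

    crop_cfg = replace(cfg, use_attention_crops=True)
    ckpts_crop, _, _ = train_two_stage(train_set, crop_cfg, backbones=backbones,
                                       input_size=size)
    scores = predict_ensemble(ckpts_crop, X_test, C, size, weights)
    rep = multilabel_metrics(scores, y_test, decision_threshold)
    rows.append({"row": "ensemble+attention_crop", **rep.to_dict()})
    return rows
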
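"""Weighted multi-label focal loss and the two-stage training protocol.

The loss per class is

.. math:: \\mathrm{FL}(p_c) = -\\alpha_c (1 - p_c)^\\gamma \\log p_c

where :math:`p_c` is the predicted probability of the *true* state of
class c (the sigmoid output if the label is 1, its complement if 0),
:math:`\\gamma` focuses training on hard examples (default 2.0) and
:math:`\\alpha_c` counteracts class imbalance.  The loss is averaged over
classes and over the batch.

Training follows a two-stage protocol: stage 1 fits one base network on
the full images and uses its class-activation maps to cut lesion crops;
stage 2 fits each ensemble backbone on each cross-validation fold of the
enlarged dataset (originals + attention crops + classic augmentations),
yielding ``n_backbones x n_folds`` checkpoints that are bagged at
prediction time.  Optimisation uses Adam with reduce-on-plateau (factor
0.1 from 1e-4 down to 1e-7, patience 8) and early stopping after 20
epochs without validation improvement, restoring the best checkpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cropping import attention_crop_dataset, classic_augment
from .data_io import FoldSplit, LabelledDataset, Record, make_fold_splits
from .models import build_backbone
from .nn import Adam, Network

__all__ = [
    "FocalLossConfig",
    "TrainConfig",
    "focal_loss",
    "focal_loss_grad",
    "class_weights_from_frequencies",
    "ReduceLROnPlateau",
    "lr_schedule_step",
    "EarlyStopper",
    "early_stopper_step",
    "fit_network",
    "train_two_stage",
    "Checkpoint",
]

logger = logging.getLogger(__name__)

_P_EPS = 1e-7  # probability clamp before log


@dataclass
class FocalLossConfig:
    gamma: float = 2.0
    alpha: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        a = np.asarray(self.alpha, dtype=np.float64)
        if (a <= 0).any():
            raise ValueError("all class weights alpha must be > 0")


@dataclass
class TrainConfig:
    input_size: int = 224
    epochs: int = 200
    batch_size: int = 16
    lr_init: float = 1e-4
    lr_floor: float = 1e-7
    lr_factor: float = 0.1
    lr_patience_epochs: int = 8
    early_stop_patience: int = 20
    folds: int = 5
    val_fraction: float = 0.2
    gamma: float = 2.0
    use_class_weights: bool = True
    theta: float = 128.0
    attention_source: str = "gradcam"
    use_attention_crops: bool = True
    use_classic_augment: bool = True
    freeze_backbone_stage: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lr_floor <= self.lr_init):
            raise ValueError("need 0 < lr_floor <= lr_init")
        if not (0 < self.lr_factor < 1):
            raise ValueError("lr_factor must be in (0, 1)")
        if self.lr_patience_epochs < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")


def _true_class_prob(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pc = np.where(np.asarray(y) == 1, p, 1.0 - p)
    return np.clip(pc, _P_EPS, 1.0 - _P_EPS)


def focal_loss(p: np.ndarray, y: np.ndarray, cfg: FocalLossConfig | None = None) -> float:
    """Mean weighted focal loss over all (sample, class) cells."""
    cfg = cfg or FocalLossConfig()
    pc = _true_class_prob(p, y)
    alpha = np.broadcast_to(np.asarray(cfg.alpha, dtype=np.float64), pc.shape)
    terms = -alpha * (1.0 - pc) ** cfg.gamma * np.log(pc)
    return float(terms.mean())


def focal_loss_grad(logits: np.ndarray, y: np.ndarray,
                    cfg: FocalLossConfig | None = None) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the pre-sigmoid logits."""
    cfg = cfg or FocalLossConfig()
    logits = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y)
    p = 1.0 / (1.0 + np.exp(-logits))
    pc = _true_class_prob(p, y)
    alpha = np.broadcast_to(np.asarray(cfg.alpha, dtype=np.float64), pc.shape)
    g = cfg.gamma
    loss = float((-alpha * (1.0 - pc) ** g * np.log(pc)).mean())
    # dFL/dpc, then dpc/dlogit = +-pc(1-pc) depending on the label
    dl_dpc = alpha * ((1.0 - pc) ** g * (-1.0 / pc)
                      + g * (1.0 - pc) ** (g - 1.0) * np.log(pc))
    sign = np.where(y == 1, 1.0, -1.0)
    grad = dl_dpc * sign * pc * (1.0 - pc) / pc.size
    return loss, grad


def class_weights_from_frequencies(dataset: LabelledDataset | np.ndarray) -> np.ndarray:
    """Inverse-frequency weights ``alpha_c ∝ n / (C * max(n_c, 1))``, mean 1."""
    labels = dataset.label_matrix() if isinstance(dataset, LabelledDataset) else np.asarray(dataset)
    n, C = labels.shape
    counts = np.maximum(labels.sum(axis=0), 1)
    alpha = n / (C * counts)
    return alpha / alpha.mean()


@dataclass
class ReduceLROnPlateau:
    """Multiply the LR by ``factor`` after ``patience`` epochs without improvement."""

    lr: float = 1e-4
    factor: float = 0.1
    patience: int = 8
    floor: float = 1e-7
    best: float = np.inf
    bad_epochs: int = 0

    def step(self, val_loss: float) -> float:
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr = max(self.lr * self.factor, self.floor)
                self.bad_epochs = 0
        return self.lr


def lr_schedule_step(state: ReduceLROnPlateau, epoch_val_loss: float) -> float:
    return state.step(epoch_val_loss)


@dataclass
class EarlyStopper:
    """Stop after ``patience`` epochs without a new best validation loss."""

    patience: int = 20
    best: float = np.inf
    bad_epochs: int = 0

    def step(self, val_loss: float) -> tuple[bool, bool]:
        """Returns ``(continue_training, is_new_best)``."""
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
            return True, True
        self.bad_epochs += 1
        return self.bad_epochs < self.patience, False


def early_stopper_step(state: EarlyStopper, epoch_val_loss: float) -> tuple[bool, bool]:
    return state.step(epoch_val_loss)


def fit_network(net: Network, X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
                rng: np.random.Generator, X_val: np.ndarray | None = None,
                y_val: np.ndarray | None = None, alpha: np.ndarray | float = 1.0,
                ) -> list[dict]:
    """Train one network in place; returns the per-epoch history.

    ``X`` is ``(n, 3, H, W)`` float, ``y`` ``(n, C)`` binary.  Without an
    explicit validation set, ``val_fraction`` of the data is held out.
    The best-validation-loss parameters are restored at the end.
    """
    n = X.shape[0]
    if X_val is None:
        n_val = max(int(round(n * cfg.val_fraction)), 1) if n > 4 else 0
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]
        if n_val == 0:
            val_idx = train_idx  # tiny datasets validate on the training data
        X_val, y_val = X[val_idx], y[val_idx]
        X, y = X[train_idx], y[train_idx]
        n = X.shape[0]

    loss_cfg = FocalLossConfig(gamma=cfg.gamma, alpha=alpha)
    opt = Adam(net, lr=cfg.lr_init)
    sched = ReduceLROnPlateau(lr=cfg.lr_init, factor=cfg.lr_factor,
                              patience=cfg.lr_patience_epochs, floor=cfg.lr_floor)
    stopper = EarlyStopper(patience=cfg.early_stop_patience)
    best_state = net.state_dict()
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        train_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = net.forward(X[idx])
            loss, grad = focal_loss_grad(logits, y[idx], loss_cfg)
            net.zero_grad()
            net.backward(grad)
            opt.step()
            train_losses.append(loss)
        val_logits = net.forward(X_val)
        val_loss = focal_loss_grad(val_logits, y_val, loss_cfg)[0]
        opt.lr = sched.step(val_loss)
        go_on, is_best = stopper.step(val_loss)
        if is_best:
            best_state = net.state_dict()
        history.append({"epoch": epoch, "lr": opt.lr,
                        "train_loss": float(np.mean(train_losses)),
                        "val_loss": float(val_loss)})
        if not go_on:
            break
    net.load_state_dict(best_state)
    return history


@dataclass
class Checkpoint:
    backbone: str
    fold: int
    state: list[np.ndarray]
    history: list[dict] = field(default_factory=list)


def _dataset_arrays(dataset: LabelledDataset) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([np.moveaxis(dataset.get_image(i), -1, 0) for i in range(len(dataset))])
    return X, dataset.label_matrix().astype(np.float64)


def train_two_stage(dataset: LabelledDataset, cfg: TrainConfig,
                    backbones: tuple[str, ...] = ("vgg19", "resnet50"),
                    input_size: tuple[int, int] | None = None,
                    ) -> tuple[list[Checkpoint], LabelledDataset, dict]:
    """Stage 1: base network + attention crops; stage 2: per-fold ensemble.

    Returns (checkpoints, augmented dataset, run manifest).  The stage-1
    crop generator is the first backbone in ``backbones``; stage 2 yields
    ``len(backbones) * cfg.folds`` checkpoints.
    """
    if len(dataset) < cfg.folds:
        raise ValueError(f"need at least folds={cfg.folds} records, got {len(dataset)}")
    rng = np.random.default_rng(cfg.seed)
    img0 = dataset.get_image(0)
    size = input_size or img0.shape[:2]
    C = dataset.n_classes
    alpha = class_weights_from_frequencies(dataset) if cfg.use_class_weights else 1.0
    manifest: dict = {"seed": cfg.seed, "backbones": list(backbones), "folds": cfg.folds,
                      "n_records": len(dataset), "theta": cfg.theta}

    # ---- stage 1: base network on the full images, then attention crops
    stage1 = build_backbone(backbones[0], C, input_size=size,
                            seed=int(rng.integers(2 ** 31)))
    X, y = _dataset_arrays(dataset)
    stage1_hist = fit_network(stage1, X, y, cfg, rng, alpha=alpha)
    if cfg.use_attention_crops:
        augmented, provenance = attention_crop_dataset(
            stage1, dataset, theta=cfg.theta, source=cfg.attention_source,
            target_size=size)
    else:
        augmented, provenance = dataset, []
    manifest["stage1_epochs"] = len(stage1_hist)
    manifest["n_crops"] = len(provenance)
    manifest["crop_provenance"] = provenance

    # ---- classic augmentation: one extra copy per record
    records = list(augmented.records)
    if cfg.use_classic_augment:
        for i, rec in enumerate(augmented.records):
            img = classic_augment(augmented.get_image(i), rng)
            records.append(Record(image_id=f"{rec.image_id}_aug",
                                  labels=rec.labels.copy(), image=img))
    train_set = LabelledDataset(records=records, class_names=list(dataset.class_names))
    manifest["n_train_records"] = len(train_set)
    manifest["record_ids"] = [r.image_id for r in train_set.records]

    # ---- stage 2: every backbone on every fold
    Xa, ya = _dataset_arrays(train_set)
    split = make_fold_splits(len(train_set), cfg.folds, seed=int(rng.integers(2 ** 31)))
    manifest["fold_assignments"] = split.assignments.tolist()
    checkpoints: list[Checkpoint] = []
    for name in backbones:
        for fold in range(cfg.folds):
            tr, va = split.fold_indices(fold)
            net = build_backbone(name, C, input_size=size,
                                 seed=int(rng.integers(2 ** 31)))
            hist = fit_network(net, Xa[tr], ya[tr], cfg, rng,
                               X_val=Xa[va], y_val=ya[va], alpha=alpha)
            checkpoints.append(Checkpoint(backbone=name, fold=fold,
                                          state=net.state_dict(), history=hist))
    manifest["n_checkpoints"] = len(checkpoints)
    return checkpoints, train_set, manifest
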
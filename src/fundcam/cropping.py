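"""Attention-guided lesion cropping and classic photometric augmentation.

An attention map is byte-scaled to [0, 255], thresholded at θ into a
binary mask, and the smallest circumscribed rectangle of the mask is cut
from the original image and bilinearly resized back to the model input
size.  The crop inherits the full label vector of its source image, which
is how the augmented dataset is assembled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize, rotate

from .attention import attention_map_for_classes
from .data_io import LabelledDataset, Record
from .nn import Network

__all__ = [
    "BoundingBox",
    "scale_to_byte",
    "threshold_mask",
    "min_bounding_rect",
    "crop_and_resize",
    "attention_box",
    "attention_crop_dataset",
    "classic_augment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open: [x, x+w) columns, [y, y+h) rows."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> int:
        return self.w * self.h


def scale_to_byte(values: np.ndarray) -> np.ndarray:
    """Min-max scale a map to [0, 255]; constant maps go to all-zero."""
    values = np.asarray(values, dtype=np.float64)
    if not np.isfinite(values).all():
        raise ValueError("attention map contains non-finite values")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    # clip guards one-ulp overshoot of the exact 255 endpoint
    return np.clip((values - lo) * (255.0 / (hi - lo)), 0.0, 255.0)


def threshold_mask(bytemap: np.ndarray, theta: float) -> np.ndarray:
    """Binary mask: 1 strictly where the byte-scaled map exceeds θ ∈ [0, 255]."""
    if not 0 <= theta <= 255:
        raise ValueError(f"threshold θ={theta} outside [0, 255]")
    return (np.asarray(bytemap) > theta).astype(np.uint8)


def min_bounding_rect(mask: np.ndarray) -> BoundingBox | None:
    """Smallest circumscribed rectangle of the mask's 1-pixels.

    Returns ``None`` for an all-zero mask (the explicit empty signal).
    """
    mask = np.asarray(mask)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        return None
    cols = np.flatnonzero(mask.any(axis=0))
    y0, y1 = int(rows[0]), int(rows[-1])
    x0, x1 = int(cols[0]), int(cols[-1])
    return BoundingBox(x=x0, y=y0, w=x1 - x0 + 1, h=y1 - y0 + 1)


def crop_and_resize(image: np.ndarray, box: BoundingBox,
                    target: tuple[int, int]) -> np.ndarray:
    """Cut the box from an H x W x 3 image and bilinearly resize to ``target``."""
    image = np.asarray(image)
    H, W = image.shape[:2]
    if box.x < 0 or box.y < 0 or box.x + box.w > W or box.y + box.h > H:
        raise ValueError(f"box {box} outside image bounds {(H, W)}")
    crop = image[box.y:box.y + box.h, box.x:box.x + box.w]
    if crop.shape[:2] == tuple(target):
        return crop.copy()
    return resize(crop, tuple(target), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def attention_box(model: Network, image_hwc: np.ndarray, classes: list[int],
                  theta: float = 128.0, source: str = "gradcam") -> BoundingBox | None:
    """Attention map -> byte scale -> θ mask -> smallest circumscribed rectangle."""
    chw = np.moveaxis(image_hwc, -1, 0)
    amap = attention_map_for_classes(model, chw, classes, source=source)
    mask = threshold_mask(scale_to_byte(amap), theta)
    return min_bounding_rect(mask)


def attention_crop_dataset(model: Network, dataset: LabelledDataset,
                           theta: float = 128.0, source: str = "gradcam",
                           target_size: tuple[int, int] | None = None,
                           ) -> tuple[LabelledDataset, list[dict]]:
    """Augment a dataset with one attention crop per image.

    Attention is aggregated over each image's ground-truth-positive
    classes; images with no positive label or an empty θ-mask contribute
    no crop.  Crops inherit the source image's full label vector.
    Returns the augmented dataset and a provenance list
    ``[{source_id, box, theta}, ...]`` for each crop made.
    """
    records: list[Record] = list(dataset.records)
    provenance: list[dict] = []
    for i, rec in enumerate(dataset.records):
        try:
            image = dataset.get_image(i)
        except (OSError, ValueError) as exc:
            logger.warning("skipping unreadable image %s: %s", rec.image_id, exc)
            continue
        classes = np.flatnonzero(rec.labels).tolist()
        if not classes:
            continue
        box = attention_box(model, image, classes, theta=theta, source=source)
        if box is None:
            continue
        target = tuple(target_size) if target_size is not None else image.shape[:2]
        crop = crop_and_resize(image, box, target)
        records.append(Record(image_id=f"{rec.image_id}_crop", labels=rec.labels.copy(),
                              image=crop))
        provenance.append({"source_id": rec.image_id, "box": (box.x, box.y, box.w, box.h),
                           "theta": theta})
    return LabelledDataset(records=records, class_names=list(dataset.class_names)), provenance


_DEFAULT_AUG = {
    "brightness": (0.8, 1.2),
    "gamma": (0.8, 1.25),
    "saturation": (0.8, 1.2),
    "rotation_deg": 15.0,
    "crop_keep_frac": 0.85,
    "flip_prob": 0.5,
}


def classic_augment(image: np.ndarray, rng: np.random.Generator,
                    ops: dict | None = None) -> np.ndarray:
    """Random brightness/gamma/saturation/crop/rotation/horizontal-flip.

    Output keeps the input shape.  Passing degenerate ranges (factor 1,
    rotation 0, crop_keep_frac 1, flip_prob 0) makes this the identity.
    """
    cfg = dict(_DEFAULT_AUG)
    if ops:
        unknown = set(ops) - set(cfg)
        if unknown:
            raise ValueError(f"unknown augmentation keys: {sorted(unknown)}")
        cfg.update(ops)
    img = np.asarray(image, dtype=np.float64)
    H, W = img.shape[:2]

    b = rng.uniform(*_as_range(cfg["brightness"]))
    g = rng.uniform(*_as_range(cfg["gamma"]))
    s = rng.uniform(*_as_range(cfg["saturation"]))
    if not g > 0:
        raise ValueError("gamma must be positive")
    img = np.clip(img * b, 0.0, 1.0) ** g
    gray = img.mean(axis=2, keepdims=True)
    img = np.clip(gray + s * (img - gray), 0.0, 1.0)

    angle = rng.uniform(-cfg["rotation_deg"], cfg["rotation_deg"])
    if angle != 0.0:
        img = rotate(img, angle, order=1, mode="constant", cval=0.0, preserve_range=True)

    keep = float(cfg["crop_keep_frac"])
    if not 0 < keep <= 1:
        raise ValueError("crop_keep_frac must be in (0, 1]")
    if keep < 1.0:
        frac = rng.uniform(np.sqrt(keep), 1.0)  # linear crop fraction keeps >= keep area
        ch, cw = max(int(round(H * frac)), 1), max(int(round(W * frac)), 1)
        y0 = rng.integers(0, H - ch + 1)
        x0 = rng.integers(0, W - cw + 1)
        img = crop_and_resize(img, BoundingBox(x=int(x0), y=int(y0), w=cw, h=ch), (H, W))

    if rng.random() < cfg["flip_prob"]:
        img = img[:, ::-1].copy()
    return img


def _as_range(v) -> tuple[float, float]:
    if np.isscalar(v):
        return float(v), float(v)
    lo, hi = v
    if hi < lo:
        raise ValueError(f"invalid range {v}")
    return float(lo), float(hi)
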
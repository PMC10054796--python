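"""Synthetic fundus-like images with planted, per-class lesion blobs.

Real fundus photographs are a bright, roughly circular retinal field on a
black background, with diseases appearing as localised structures
(haemorrhages, drusen, exudates) inside the field.  The generator emulates
exactly the features the attention pipeline depends on:

* a circular field on an exactly-black background (pixels outside the
  field are 0),
* independent per-class binary labels with configurable prevalence,
* for every positive label, one or more Gaussian-profile blob lesions
  drawn in a class-distinctive colour, with the exact pixel mask of every
  blob retained so that localisation can be scored against ground truth.

It makes no attempt at photorealism: there is no vessel tree, no optic
disc, and lesion appearance within a class varies only in position, size
and brightness.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import LabelledDataset, Record, save_image, write_label_table

__all__ = ["SyntheticSpec", "SyntheticSample", "generate_sample", "generate_dataset"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic image distribution.

    Defaults give a 224-pixel image (the pipeline's native input size)
    whose field fills 90% of the frame, one or two lesions per positive
    class with radii 8-18 px, and mild sensor noise.
    """

    image_size: int = 224
    n_classes: int = 3
    label_prevalence: float | tuple[float, ...] = 0.4
    blob_count: tuple[int, int] = (1, 2)        # inclusive range per positive class
    blob_radius: tuple[float, float] = (8.0, 18.0)
    blob_intensity: tuple[float, float] = (0.45, 0.8)
    field_radius_frac: float = 0.45             # of image_size
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        prev = self.prevalence_vector()
        if ((prev < 0) | (prev > 1)).any():
            raise ValueError("label prevalence must lie in [0, 1]")
        lo, hi = self.blob_radius
        if not (0 < lo <= hi):
            raise ValueError("blob_radius must be a positive (lo, hi) range")
        if hi >= self.field_radius_frac * self.image_size:
            raise ValueError("blob radius must be smaller than the field radius")
        if not (1 <= self.blob_count[0] <= self.blob_count[1]):
            raise ValueError("blob_count must be an integer range with lo >= 1")

    def prevalence_vector(self) -> np.ndarray:
        p = np.asarray(self.label_prevalence, dtype=np.float64)
        if p.ndim == 0:
            p = np.full(self.n_classes, float(p))
        if p.shape != (self.n_classes,):
            raise ValueError("label_prevalence must be scalar or length n_classes")
        return p


@dataclass
class SyntheticSample:
    image: np.ndarray        # H x W x 3 float in [0, 1]
    labels: np.ndarray       # binary length-C vector
    lesion_masks: np.ndarray  # C x H x W boolean, union of the class's blobs


def class_color(c: int, n_classes: int) -> np.ndarray:
    """Saturated distinctive hue per class, spaced around the colour wheel."""
    # hues kept in [0.25, 0.85]: away from the warm background colour
    hue = 0.25 + 0.6 * (c / max(n_classes, 1))
    return np.asarray(colorsys.hsv_to_rgb(hue, 0.9, 1.0))


_FIELD_COLOR = np.array([0.72, 0.38, 0.10])  # warm retinal background


def generate_sample(spec: SyntheticSpec, rng: np.random.Generator,
                    labels: np.ndarray | None = None) -> SyntheticSample:
    """Draw one image; pass ``labels`` to render a fixed label vector."""
    size = spec.image_size
    yy, xx = np.mgrid[0:size, 0:size]
    center = (size - 1) / 2.0
    r_field = spec.field_radius_frac * size
    dist = np.hypot(yy - center, xx - center)
    field = dist <= r_field

    if labels is None:
        labels = (rng.random(spec.n_classes) < spec.prevalence_vector()).astype(np.int64)
    labels = np.asarray(labels, dtype=np.int64)

    # base field: warm colour with gentle radial vignetting plus noise
    vignette = 1.0 - 0.25 * (dist / r_field) ** 2
    image = _FIELD_COLOR[None, None, :] * vignette[:, :, None]
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)

    masks = np.zeros((spec.n_classes, size, size), dtype=bool)
    for c in range(spec.n_classes):
        if labels[c] != 1:
            continue
        color = class_color(c, spec.n_classes)
        n_blobs = int(rng.integers(spec.blob_count[0], spec.blob_count[1] + 1))
        for _ in range(n_blobs):
            radius = rng.uniform(*spec.blob_radius)
            amp = rng.uniform(*spec.blob_intensity)
            # place the whole blob inside the field
            rho = rng.uniform(0.0, max(r_field - radius, 0.0))
            ang = rng.uniform(0.0, 2 * np.pi)
            cy = center + rho * np.sin(ang)
            cx = center + rho * np.cos(ang)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            profile = amp * np.exp(-d2 / (2.0 * (radius / 2.0) ** 2))
            image = image + profile[:, :, None] * color[None, None, :]
            masks[c] |= d2 <= radius ** 2

    image = np.clip(image, 0.0, 1.0)
    image[~field] = 0.0  # exact black outside the circular field
    masks &= field[None]
    return SyntheticSample(image=image, labels=labels, lesion_masks=masks)


def generate_dataset(spec: SyntheticSpec, n: int, out_dir: str | Path | None = None,
                     prefix: str = "syn") -> tuple[LabelledDataset, np.ndarray]:
    """Draw ``n`` samples; optionally write PNGs + a label CSV under ``out_dir``.

    Returns the dataset (images kept in memory) and the ``n x C x H x W``
    boolean lesion-mask array for oracle tests.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(spec.seed)
    class_names = [f"class_{c}" for c in range(spec.n_classes)]
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    records, all_masks = [], []
    for i in range(n):
        sample = generate_sample(spec, rng)
        img_id = f"{prefix}_{i:04d}"
        path = None
        if out_dir is not None:
            path = out_dir / f"{img_id}.png"
            save_image(sample.image, path)
        records.append(Record(image_id=img_id, labels=sample.labels,
                              path=path, image=sample.image))
        all_masks.append(sample.lesion_masks)

    dataset = LabelledDataset(records=records, class_names=class_names)
    if out_dir is not None:
        write_label_table(dataset, out_dir / "labels.csv")
    return dataset, np.stack(all_masks)
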
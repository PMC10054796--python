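"""Image and multi-label table I/O, plus k-fold bagging splits.

The label table follows the RFMiD convention: a CSV whose first column is
the image id and whose remaining columns are binary disease indicators,
one column per category.  A ``Disease_Risk`` column, when present, is an
ordinary class column unless the caller excludes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "DataIOError",
    "MissingIdColumnError",
    "NonBinaryLabelError",
    "DuplicateIdError",
    "FoldConfigError",
    "Record",
    "LabelledDataset",
    "FoldSplit",
    "read_label_table",
    "write_label_table",
    "load_image",
    "save_image",
    "make_fold_splits",
]


class DataIOError(ValueError):
    """Base class for label-table parsing problems."""


class MissingIdColumnError(DataIOError):
    pass


class NonBinaryLabelError(DataIOError):
    pass


class DuplicateIdError(DataIOError):
    pass


class FoldConfigError(ValueError):
    """Fold request is inconsistent with the dataset size."""


@dataclass
class Record:
    """One labelled image: id, an on-disk path and/or an in-memory array."""

    image_id: str
    labels: np.ndarray  # binary vector, length C
    path: Path | None = None
    image: np.ndarray | None = None  # H x W x 3 float in [0, 1]


@dataclass
class LabelledDataset:
    records: list[Record]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DuplicateIdError("duplicate image ids in dataset")
        C = len(self.class_names)
        for r in self.records:
            r.labels = np.asarray(r.labels, dtype=np.int64)
            if r.labels.shape != (C,):
                raise DataIOError(
                    f"record {r.image_id!r}: label length {r.labels.shape} != C={C}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def label_matrix(self) -> np.ndarray:
        return np.stack([r.labels for r in self.records]) if self.records else \
            np.zeros((0, self.n_classes), dtype=np.int64)

    def get_image(self, i: int) -> np.ndarray:
        """Return record i's image as H x W x 3 float in [0, 1], loading lazily."""
        r = self.records[i]
        if r.image is None:
            if r.path is None:
                raise DataIOError(f"record {r.image_id!r} has neither image nor path")
            r.image = load_image(r.path)
        return r.image

    def images_array(self) -> np.ndarray:
        return np.stack([self.get_image(i) for i in range(len(self))])


@dataclass
class FoldSplit:
    k: int
    assignments: np.ndarray  # per-record fold index in [0, k)

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train indices, validation indices) for one fold."""
        val = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, val


def read_label_table(path: str | Path, image_dir: str | Path | None = None,
                     id_column: str | None = None, check_images: bool = False,
                     exclude_columns: tuple[str, ...] = ()) -> LabelledDataset:
    """Parse an RFMiD-style CSV into a :class:`LabelledDataset`.

    The id column is the first column unless ``id_column`` names another.
    Remaining columns (minus ``exclude_columns``) are binary classes in
    header order.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise MissingIdColumnError("label table needs an id column plus >=1 class column")
    id_col = id_column or df.columns[0]
    if id_col not in df.columns:
        raise MissingIdColumnError(f"id column {id_col!r} not in header")
    class_names = [c for c in df.columns if c != id_col and c not in exclude_columns]
    if not class_names:
        raise DataIOError("no class columns after exclusions")
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise DuplicateIdError(f"duplicate image ids: {dupes}")
    labels = df[class_names].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        bad = sorted({str(v) for v in np.unique(labels) if v not in (0, 1)})
        raise NonBinaryLabelError(f"non-binary label values: {bad}")
    image_dir = Path(image_dir) if image_dir is not None else None
    records = []
    for img_id, row in zip(ids, labels.astype(np.int64)):
        p = _resolve_image_path(image_dir, img_id) if image_dir is not None else None
        if check_images and (p is None or not p.exists()):
            raise DataIOError(f"image file for id {img_id!r} not found under {image_dir}")
        records.append(Record(image_id=img_id, labels=row, path=p))
    return LabelledDataset(records=records, class_names=class_names)


def _resolve_image_path(image_dir: Path, img_id: str) -> Path:
    for ext in ("", ".png", ".jpg", ".jpeg", ".PNG", ".JPG"):
        cand = image_dir / f"{img_id}{ext}"
        if cand.exists():
            return cand
    return image_dir / f"{img_id}.png"


def write_label_table(dataset: LabelledDataset, path: str | Path,
                      id_column: str = "ID") -> None:
    """Write the dataset's id/label matrix back to CSV (round-trip safe)."""
    df = pd.DataFrame(dataset.label_matrix(), columns=dataset.class_names)
    df.insert(0, id_column, [r.image_id for r in dataset.records])
    df.to_csv(path, index=False)


def load_image(path: str | Path) -> np.ndarray:
    """Decode PNG/JPEG to H x W x 3 float64 in [0, 1]; grayscale is replicated."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    return arr


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write an H x W x 3 float image in [0, 1] as 8-bit PNG/JPEG."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255.0).round().astype(np.uint8)).save(path)


def make_fold_splits(n: int, k: int = 5, seed: int = 0) -> FoldSplit:
    """Random balanced k-fold partition (fold sizes differ by at most one)."""
    if k < 2:
        raise FoldConfigError(f"need k >= 2 folds, got {k}")
    if n < k:
        raise FoldConfigError(f"cannot split n={n} records into k={k} non-empty folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=np.int64)
    # first n % k folds get the extra record
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        assignments[order[start:start + size]] = fold
        start += size
    return FoldSplit(k=k, assignments=assignments)
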
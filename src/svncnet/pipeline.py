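"""Slice <-> volume data pipeline.

3D CT volumes (NIfTI) are decomposed into axial (z-axis) 2D slices, slices
whose masks carry no foreground are excluded, the remainder is resized to
the network's input size, and predictions are reassembled into 3D masks at
the original geometry. Fold assignment for the three evaluation rounds
(E1-E3) partitions slices into ten folds stratified by foreground area,
with each round using 7 folds for training, 2 for validation and 1 for
testing.

Arrays are indexed (z, y, x), 0-based; NIfTI files store (x, y, z) and are
transposed on load. Orientation metadata (the affine) is carried opaquely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

__all__ = [
    "Volume", "SliceRecord", "FoldAssignment", "EVALUATION_ROUNDS",
    "load_volume", "save_volume", "normalize_volume", "slice_volume_z",
    "filter_labeled", "resize_slice", "make_folds", "evaluation_rounds",
    "reconstruct_volume", "records_manifest",
]


@dataclass
class Volume:
    """A 3D image with optional paired binary mask, (z, y, x) indexed."""

    image: np.ndarray
    mask: np.ndarray | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    identifier: str = "volume"
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 3:
            raise ValueError("image must be a 3D (z, y, x) array")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.image.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != image shape {self.image.shape}")
            if not np.isin(np.unique(self.mask), (0, 1)).all():
                raise ValueError("mask values must be in {0, 1}")

    @property
    def depth(self) -> int:
        return self.image.shape[0]


@dataclass
class SliceRecord:
    """One axial slice with provenance for 3D reconstruction."""

    volume_id: str
    z_index: int
    image: np.ndarray
    mask: np.ndarray | None = None
    original_shape: tuple[int, int] | None = None

    def __post_init__(self):
        if self.mask is not None and self.mask.shape != self.image.shape:
            raise ValueError("slice image/mask shapes differ")
        if self.original_shape is None:
            self.original_shape = tuple(self.image.shape)


@dataclass
class FoldAssignment:
    """Mapping of slice records to folds F1..Fk plus the round plan."""

    fold_of_record: list[str]
    k: int = 10
    rounds: dict = field(default_factory=dict)

    def indices_of(self, fold: str) -> list[int]:
        return [i for i, f in enumerate(self.fold_of_record) if f == fold]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_volume(path, mask_path=None, identifier: str | None = None) -> Volume:
    """Load a NIfTI volume (and optional mask, binarized as >0 -> 1)."""
    try:
        img = nib.load(str(path))
    except Exception as e:  # noqa: BLE001
        raise IOError(f"cannot read NIfTI volume {path}: {e}") from e
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    image = np.ascontiguousarray(data.T.astype(np.float32))  # (x,y,z) -> (z,y,x)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    mask = None
    if mask_path is not None:
        try:
            mimg = nib.load(str(mask_path))
        except Exception as e:  # noqa: BLE001
            raise IOError(f"cannot read NIfTI mask {mask_path}: {e}") from e
        mdata = np.asanyarray(mimg.dataobj)
        if mdata.shape != data.shape:
            raise ValueError(
                f"mask shape {mdata.shape} does not match image shape {data.shape}")
        mask = np.ascontiguousarray((mdata.T > 0).astype(np.uint8))
    name = identifier or str(path).split("/")[-1].split(".")[0]
    return Volume(image=image, mask=mask, spacing=spacing, identifier=name,
                  affine=np.asarray(img.affine))


def save_volume(volume: Volume, path, what: str = "image") -> None:
    """Write the image or mask of a Volume as NIfTI ((z,y,x) -> (x,y,z))."""
    arr = volume.image if what == "image" else volume.mask
    if arr is None:
        raise ValueError(f"volume has no {what}")
    affine = volume.affine if volume.affine is not None else np.diag(
        [volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr.T), affine), str(path))


def normalize_volume(volume: Volume, window: tuple[float, float] | None = None) -> Volume:
    """Per-volume min-max normalization to [0, 1], after an optional
    intensity (HU) window clip."""
    img = volume.image.astype(np.float32)
    if window is not None:
        img = np.clip(img, window[0], window[1])
    lo, hi = float(img.min()), float(img.max())
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return Volume(image=img, mask=volume.mask, spacing=volume.spacing,
                  identifier=volume.identifier, affine=volume.affine)


# ---------------------------------------------------------------------------
# Slicing, filtering, resizing
# ---------------------------------------------------------------------------

def slice_volume_z(volume: Volume) -> list[SliceRecord]:
    """One record per z index, ascending."""
    records = []
    for z in range(volume.depth):
        records.append(SliceRecord(
            volume_id=volume.identifier,
            z_index=z,
            image=volume.image[z],
            mask=None if volume.mask is None else volume.mask[z],
            original_shape=volume.image.shape[1:],
        ))
    return records


def filter_labeled(records: list[SliceRecord]) -> list[SliceRecord]:
    """Keep slices whose mask has at least one foreground pixel."""
    for r in records:
        if r.mask is None:
            raise ValueError(f"record {r.volume_id}/z={r.z_index} lacks a mask")
    kept = [r for r in records if int(r.mask.sum()) > 0]
    if records and not kept:
        logger.warning("all %d slices have empty masks; nothing retained", len(records))
    return kept


def resize_slice(record: SliceRecord, target: int = 512) -> SliceRecord:
    """Resize to target x target: bilinear for the image, nearest-neighbour
    (re-binarized) for the mask; the pre-resize shape is retained."""
    if target <= 0:
        raise ValueError("target size must be positive")
    if record.image.shape == (target, target):
        return record
    img = _sk_resize(record.image.astype(np.float32), (target, target),
                     order=1, anti_aliasing=True, preserve_range=True).astype(np.float32)
    mask = None
    if record.mask is not None:
        mask = _sk_resize(record.mask.astype(np.uint8), (target, target),
                          order=0, anti_aliasing=False, preserve_range=True)
        mask = (mask > 0.5).astype(np.uint8)
    return SliceRecord(volume_id=record.volume_id, z_index=record.z_index,
                       image=img, mask=mask,
                       original_shape=record.original_shape)


# ---------------------------------------------------------------------------
# Folds and evaluation rounds
# ---------------------------------------------------------------------------

EVALUATION_ROUNDS = {
    "E1": {"train": ("F1", "F3", "F4", "F6", "F7", "F8", "F10"),
           "val": ("F2", "F5"), "test": ("F9",)},
    "E2": {"train": ("F2", "F4", "F5", "F6", "F7", "F9", "F10"),
           "val": ("F1", "F8"), "test": ("F3",)},
    "E3": {"train": ("F1", "F2", "F3", "F5", "F7", "F8", "F9"),
           "val": ("F4", "F6"), "test": ("F10",)},
}


def make_folds(records: list[SliceRecord], k: int = 10, seed: int = 0,
               group_by_volume: bool = False) -> FoldAssignment:
    """Partition records into k balanced folds, stratified by quartile of
    per-slice foreground area (deterministic given seed).

    With group_by_volume, whole volumes are dealt to folds instead of
    slices, preventing a patient's slices from straddling splits.
    """
    n = len(records)
    if n < k:
        raise ValueError(f"need at least {k} records to build {k} folds, got {n}")
    rng = np.random.default_rng(seed)
    fold_of = [""] * n

    if group_by_volume:
        vols = sorted({r.volume_id for r in records})
        order = rng.permutation(len(vols))
        vol_fold = {vols[j]: f"F{(i % k) + 1}" for i, j in enumerate(order)}
        for i, r in enumerate(records):
            fold_of[i] = vol_fold[r.volume_id]
    else:
        areas = np.array([0 if r.mask is None else int(r.mask.sum()) for r in records])
        qs = np.quantile(areas, [0.25, 0.5, 0.75])
        bins = np.digitize(areas, qs)
        order = []
        for b in range(4):
            idx = np.flatnonzero(bins == b)
            order.extend(rng.permutation(idx).tolist())
        for pos, i in enumerate(order):
            fold_of[i] = f"F{(pos % k) + 1}"

    return FoldAssignment(fold_of_record=fold_of, k=k,
                          rounds=evaluation_rounds_for(k))


def evaluation_rounds_for(k: int) -> dict:
    return dict(EVALUATION_ROUNDS) if k == 10 else {}


def evaluation_rounds(assignment: FoldAssignment) -> dict:
    """The three fixed evaluation rounds (7 train / 2 val / 1 test folds)."""
    if assignment.k != 10:
        raise ValueError("evaluation rounds require a 10-fold assignment")
    folds = {f"F{i + 1}" for i in range(assignment.k)}
    missing = folds - set(assignment.fold_of_record)
    if missing:
        raise ValueError(f"folds with no records: {sorted(missing)}")
    return dict(EVALUATION_ROUNDS)


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------

def reconstruct_volume(predicted_slices: list[SliceRecord], depth: int,
                       original_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Stack per-slice binary predictions back into a (depth, H, W) mask.

    Slices are resized back to the original in-plane shape with
    nearest-neighbour interpolation; z positions with no prediction (e.g.
    slices dropped by the empty-mask filter) are filled with background.
    """
    if original_shape is None:
        original_shape = predicted_slices[0].original_shape
    out = np.zeros((depth, *original_shape), dtype=np.uint8)
    seen = set()
    for r in predicted_slices:
        key = (r.volume_id, r.z_index)
        if key in seen:
            raise ValueError(f"duplicate prediction for {key}")
        seen.add(key)
        if not 0 <= r.z_index < depth:
            raise ValueError(f"z_index {r.z_index} outside volume depth {depth}")
        m = r.mask if r.mask is not None else binarized(r.image)
        if m.shape != tuple(original_shape):
            m = _sk_resize(m.astype(np.uint8), original_shape, order=0,
                           anti_aliasing=False, preserve_range=True)
            m = (m > 0.5).astype(np.uint8)
        out[r.z_index] = m
    return out


def binarized(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return (np.asarray(probabilities) >= threshold).astype(np.uint8)


def records_manifest(records: list[SliceRecord],
                     assignment: FoldAssignment | None = None) -> pd.DataFrame:
    """Tabular manifest (volume_id, z_index, foreground area, fold)."""
    rows = []
    for i, r in enumerate(records):
        rows.append({
            "volume_id": r.volume_id,
            "z_index": r.z_index,
            "foreground_area": 0 if r.mask is None else int(r.mask.sum()),
            "fold": assignment.fold_of_record[i] if assignment else "",
        })
    return pd.DataFrame(rows)
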
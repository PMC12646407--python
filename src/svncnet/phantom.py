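"""Synthetic CT-like phantoms: one bright ellipsoidal organ per volume.

Each phantom emulates the gross structure of an abdominal CT spleen study
on a normalized intensity scale: a soft-tissue background level (0.3), a
brighter ellipsoidal organ (0.7), additive Gaussian noise, and a paired
binary mask. A guaranteed fraction of z-slices carries no foreground so the
empty-mask filter in the pipeline is exercised. Geometry is sampled before
the noise field, so changing only noise_sigma never changes the mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pipeline import (SliceRecord, Volume, filter_labeled, normalize_volume,
                       records_manifest, resize_slice, slice_volume_z)

__all__ = ["PhantomConfig", "generate_phantom", "phantom_dataset"]


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (24, 96, 96)  # (depth, height, width) voxels
    n_volumes: int = 4
    background_level: float = 0.3
    organ_level: float = 0.7
    noise_sigma: float = 0.05
    # per-axis (min, max) semi-axes in voxels, (z, y, x) order
    semi_axes_range: tuple[tuple[float, float], ...] = ((4.0, 7.0), (14.0, 26.0), (14.0, 26.0))
    center_jitter: float = 8.0
    empty_slice_margin: float = 0.25
    seed: int = 0

    def __post_init__(self):
        d, h, w = self.shape
        if self.organ_level == self.background_level:
            raise ValueError("organ_level must differ from background_level")
        if not 0.0 <= self.empty_slice_margin < 1.0:
            raise ValueError("empty_slice_margin must lie in [0, 1)")
        if len(self.semi_axes_range) != 3:
            raise ValueError("semi_axes_range needs (z, y, x) entries")
        (az_lo, az_hi), (ay_lo, ay_hi), (ax_lo, ax_hi) = self.semi_axes_range
        if 2 * az_hi >= d * (1.0 - self.empty_slice_margin):
            raise ValueError("z semi-axis too large for the requested empty-slice margin")
        if 2 * ay_hi >= h or 2 * ax_hi >= w:
            raise ValueError("in-plane semi-axes do not fit inside the volume")
        if min(az_lo, ay_lo, ax_lo) <= 0:
            raise ValueError("semi-axes must be positive")


def _sample_geometry(cfg: PhantomConfig, rng: np.random.Generator):
    d, h, w = cfg.shape
    (az_lo, az_hi), (ay_lo, ay_hi), (ax_lo, ax_hi) = cfg.semi_axes_range
    az = rng.uniform(az_lo, az_hi)
    ay = rng.uniform(ay_lo, ay_hi)
    ax = rng.uniform(ax_lo, ax_hi)
    # keep ceil(margin * depth) slices guaranteed empty: confine the organ's
    # z-extent to a window of length depth - required_empty
    required_empty = math.ceil(cfg.empty_slice_margin * d)
    span = d - required_empty
    lo = az + 0.5
    hi = span - az - 0.5
    start = rng.uniform(0, d - span) if d > span else 0.0
    cz = start + (rng.uniform(lo, hi) if hi > lo else span / 2.0)
    cy = h / 2.0 + rng.uniform(-cfg.center_jitter, cfg.center_jitter)
    cx = w / 2.0 + rng.uniform(-cfg.center_jitter, cfg.center_jitter)
    return (cz, cy, cx), (az, ay, ax)


def generate_phantom(config: PhantomConfig, return_geometry: bool = False):
    """Deterministically (per seed) generate n_volumes image/mask pairs.

    With return_geometry, also returns the sampled (center, semi_axes)
    per volume (useful as an analytic oracle for the voxelized mask)."""
    rng = np.random.default_rng(config.seed)
    d, h, w = config.shape
    zz, yy, xx = np.meshgrid(np.arange(d), np.arange(h), np.arange(w),
                             indexing="ij")
    volumes = []
    geometries = []
    for v in range(config.n_volumes):
        (cz, cy, cx), (az, ay, ax) = _sample_geometry(config, rng)
        geometries.append(((cz, cy, cx), (az, ay, ax)))
        ell = (((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2
               + ((xx - cx) / ax) ** 2) <= 1.0
        mask = ell.astype(np.uint8)
        noise = rng.normal(0.0, 1.0, size=config.shape)
        image = (config.background_level
                 + (config.organ_level - config.background_level) * mask
                 + config.noise_sigma * noise).astype(np.float32)
        volumes.append(Volume(
            image=image, mask=mask,
            identifier=f"phantom-{config.seed:04d}-{v:03d}",
            spacing=(1.0, 1.0, 1.0)))
    if return_geometry:
        return volumes, geometries
    return volumes


def phantom_dataset(config: PhantomConfig, target_size: int = 64):
    """Phantoms run through the training pipeline: slice along z, drop
    empty-mask slices, resize. Returns (records, manifest DataFrame)."""
    records: list[SliceRecord] = []
    for vol in generate_phantom(config):
        vol = normalize_volume(vol)
        kept = filter_labeled(slice_volume_z(vol))
        records.extend(resize_slice(r, target_size) for r in kept)
    return records, records_manifest(records)
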
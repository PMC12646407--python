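"""Training loop, volume inference, and round-based evaluation.

Training follows the recipe the architecture was designed around: Adam,
the Dice+BCE compound loss, cosine annealing with warm restarts stepped
per epoch, batch size 16 and 50 epochs at full scale (scaled down for the
phantom smoke runs). All randomness (batch shuffling, weight init) derives
from the single RunConfig seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arch import ArchConfig, SVNCNet
from .losses import LossConfig, combined_loss_and_grad
from .metrics import MetricsReport, binarize, evaluate_dataset
from .nn import Adam
from .pipeline import (FoldAssignment, SliceRecord, Volume, normalize_volume,
                       reconstruct_volume, resize_slice, slice_volume_z)
from .schedule import ScheduleConfig, schedule_over_training

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "TrainingLog", "train_model", "predict_slices",
           "predict_volume", "evaluate_round"]


@dataclass
class RunConfig:
    arch: ArchConfig = field(default_factory=ArchConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    batch_size: int = 16
    epochs: int = 50
    seed: int = 0
    round: str = "E1"
    threshold: float = 0.5

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs != self.schedule.total_epochs:
            raise ValueError(
                f"epochs ({self.epochs}) must equal the schedule's total "
                f"({self.schedule.total_epochs})")
        if self.round not in ("E1", "E2", "E3"):
            raise ValueError("round must be one of E1, E2, E3")


@dataclass
class TrainingLog:
    history: pd.DataFrame  # epoch, lr, train_loss, val_loss
    final_train_loss: float


def _stack(records: list[SliceRecord]):
    x = np.stack([r.image for r in records]).astype(np.float32)[:, None]
    y = np.stack([r.mask for r in records]).astype(np.float32)[:, None]
    return x, y


def train_model(model: SVNCNet, train_records: list[SliceRecord],
                val_records: list[SliceRecord] | None = None,
                config: RunConfig | None = None) -> TrainingLog:
    """Train in place; logs per-epoch train/validation loss and the
    learning rate. Aborts on non-finite loss."""
    cfg = config or RunConfig()
    if not train_records:
        raise ValueError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    lrs = schedule_over_training(cfg.schedule)
    opt = Adam(model.parameters(), lr=lrs[0])
    x_all, y_all = _stack(train_records)
    x_val = y_val = None
    if val_records:
        x_val, y_val = _stack(val_records)

    n = len(train_records)
    rows = []
    last = np.nan
    for epoch in range(cfg.epochs):
        opt.lr = float(lrs[epoch])
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            p = model(xb, training=True)
            loss, grad = combined_loss_and_grad(p, yb, cfg.loss)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}")
            opt.zero_grad()
            model.graph.backward(grad)
            opt.step()
            losses.append(loss)
        last = float(np.mean(losses))
        val = np.nan
        if x_val is not None:
            pv = model.predict_proba(x_val)
            val, _ = combined_loss_and_grad(pv, y_val, cfg.loss)
        rows.append({"epoch": epoch, "lr": opt.lr,
                     "train_loss": last, "val_loss": val})
        logger.info("epoch %d lr=%.2e train=%.4f val=%s", epoch, opt.lr, last,
                    f"{val:.4f}" if np.isfinite(val) else "-")
    return TrainingLog(history=pd.DataFrame(rows), final_train_loss=last)


def training_dice(model, records: list[SliceRecord],
                  threshold: float = 0.5, batch_size: int = 16) -> float:
    """Hard (thresholded) Dice over a record set, averaged per slice."""
    from .metrics import MaskPair, dsc
    vals = []
    for probs, rec in zip(predict_slices(model, records, batch_size), records):
        vals.append(dsc(MaskPair(binarize(probs, threshold), rec.mask)))
    return float(np.mean(vals))


def predict_slices(model, records: list[SliceRecord],
                   batch_size: int = 16) -> list[np.ndarray]:
    """Per-slice probability maps (evaluation mode)."""
    out = []
    for start in range(0, len(records), batch_size):
        chunk = records[start:start + batch_size]
        x = np.stack([r.image for r in chunk]).astype(np.float32)[:, None]
        p = model.predict_proba(x)
        out.extend(p[i, 0] for i in range(len(chunk)))
    return out


def predict_volume(model, volume: Volume, target_size: int | None = None,
                   threshold: float = 0.5, batch_size: int = 8,
                   window: tuple[float, float] | None = None,
                   normalize: bool = True) -> np.ndarray:
    """Slice-wise 3D inference: normalize, slice along z, resize, predict,
    threshold at 0.5 and reconstruct at the original geometry.

    normalize=False skips the per-volume min-max rescale for inputs already
    on the network's [0, 1] intensity scale (min-max would stretch a
    near-constant volume's noise across the full range).
    """
    if target_size is None:
        target_size = model.config.input_size if hasattr(model, "config") else 64
    vol = normalize_volume(volume, window=window) if normalize else volume
    records = [resize_slice(r, target_size) for r in slice_volume_z(vol)]
    probs = predict_slices(model, records, batch_size)
    preds = [SliceRecord(volume_id=r.volume_id, z_index=r.z_index,
                         image=r.image, mask=binarize(p, threshold),
                         original_shape=r.original_shape)
             for r, p in zip(records, probs)]
    return reconstruct_volume(preds, depth=volume.depth,
                              original_shape=volume.image.shape[1:])


def evaluate_round(model, records: list[SliceRecord],
                   assignment: FoldAssignment, round_name: str,
                   aggregation: str = "per_slice_mean",
                   threshold: float = 0.5) -> MetricsReport:
    """Metrics on the round's held-out test fold only; errors on any
    train/test fold overlap. Validation metrics are never reported."""
    from .pipeline import evaluation_rounds
    rounds = evaluation_rounds(assignment)
    if round_name not in rounds:
        raise ValueError(f"unknown round {round_name!r}")
    spec = rounds[round_name]
    if set(spec["train"]) & set(spec["test"]):
        raise RuntimeError(f"train/test fold overlap in round {round_name}")
    test_idx = [i for i, f in enumerate(assignment.fold_of_record)
                if f in spec["test"]]
    test_records = [records[i] for i in test_idx]
    probs = predict_slices(model, test_records)
    preds = {i: binarize(p, threshold) for i, p in zip(test_idx, probs)}
    refs = {i: test_records[j].mask for j, i in enumerate(test_idx)}
    groups = {i: test_records[j].volume_id for j, i in enumerate(test_idx)}
    return evaluate_dataset(preds, refs, aggregation=aggregation, groups=groups)
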
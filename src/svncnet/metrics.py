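"""Overlap metrics for binary segmentation masks.

IoU (Jaccard) = |A n B| / |A u B|; mIoU averages the foreground IoU with
the background IoU (computed on complemented masks), i.e. the two-class
mean; DSC = 2|A n B| / (|A| + |B|), related to IoU by the exact identity
DSC = 2*IoU / (1 + IoU).

When both masks are empty the 0/0 case is resolved to 1 (a prediction of
"nothing" against an empty reference is a perfect match); the event is
logged since the upstream empty-mask filter makes it rare.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["MaskPair", "MetricsReport", "iou", "mean_iou", "dsc",
           "dsc_from_iou", "binarize", "evaluate_dataset"]


@dataclass
class MaskPair:
    """A predicted/reference binary mask pair of equal shape."""

    predicted: np.ndarray
    reference: np.ndarray

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted)
        self.reference = np.asarray(self.reference)
        if self.predicted.shape != self.reference.shape:
            raise ValueError(
                f"shape mismatch: {self.predicted.shape} vs {self.reference.shape}")
        for name, a in (("predicted", self.predicted), ("reference", self.reference)):
            if not np.isin(np.unique(a), (0, 1)).all():
                raise ValueError(f"{name} mask must be binary (values in {{0, 1}})")


def binarize(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return (np.asarray(probabilities) >= threshold).astype(np.uint8)


def _iou_counts(a: np.ndarray, b: np.ndarray) -> float:
    inter = int(np.logical_and(a, b).sum())
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        logger.debug("IoU of two empty masks; returning 1 by convention")
        return 1.0
    return inter / union


def iou(pair: MaskPair) -> float:
    """Foreground intersection-over-union in [0, 1]."""
    return _iou_counts(pair.predicted, pair.reference)


def mean_iou(pair: MaskPair) -> float:
    """Two-class mean IoU: average of foreground and background IoU."""
    fg = _iou_counts(pair.predicted, pair.reference)
    bg = _iou_counts(1 - pair.predicted, 1 - pair.reference)
    return 0.5 * (fg + bg)


def dsc(pair: MaskPair) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|)."""
    inter = int(np.logical_and(pair.predicted, pair.reference).sum())
    total = int(pair.predicted.sum()) + int(pair.reference.sum())
    if total == 0:
        logger.debug("DSC of two empty masks; returning 1 by convention")
        return 1.0
    return 2.0 * inter / total


def dsc_from_iou(iou_value: float) -> float:
    """The exact DSC-IoU identity 2*IoU / (1 + IoU)."""
    if not 0.0 <= iou_value <= 1.0:
        raise ValueError(f"IoU must lie in [0, 1], got {iou_value}")
    return 2.0 * iou_value / (1.0 + iou_value)


@dataclass
class MetricsReport:
    per_item: pd.DataFrame
    iou: float
    miou: float
    dsc: float
    aggregation: str = "per_slice_mean"
    per_class_iou: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        df = self.per_item.copy()
        agg = {"item": "AGGREGATE", "iou": self.iou, "miou": self.miou, "dsc": self.dsc}
        pd.concat([df, pd.DataFrame([agg])], ignore_index=True).to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "aggregation": self.aggregation,
            "aggregate": {"iou": self.iou, "miou": self.miou, "dsc": self.dsc,
                          "per_class_iou": self.per_class_iou},
            "per_item": self.per_item.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def evaluate_dataset(predictions: dict, references: dict,
                     aggregation: str = "per_slice_mean",
                     groups: dict | None = None) -> MetricsReport:
    """Aggregate per-pair metrics by unweighted mean.

    predictions/references map item identifiers to binary masks. With
    aggregation "per_volume", groups must map each identifier to a volume
    id; per-pair metrics are first averaged within each volume, then across
    volumes.
    """
    if set(predictions) != set(references):
        missing = set(predictions) ^ set(references)
        raise ValueError(f"unmatched identifiers between predictions and references: {sorted(missing)[:5]}")
    if aggregation not in ("per_slice_mean", "per_volume"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    rows = []
    for key in sorted(predictions, key=str):
        pair = MaskPair(predictions[key], references[key])
        fg = _iou_counts(pair.predicted, pair.reference)
        bg = _iou_counts(1 - pair.predicted, 1 - pair.reference)
        rows.append({"item": key, "iou": fg, "background_iou": bg,
                     "miou": 0.5 * (fg + bg), "dsc": dsc(pair),
                     "group": (groups or {}).get(key, key)})
    df = pd.DataFrame(rows)
    if aggregation == "per_volume":
        agg = df.groupby("group")[["iou", "background_iou", "miou", "dsc"]].mean().mean()
    else:
        agg = df[["iou", "background_iou", "miou", "dsc"]].mean()
    return MetricsReport(
        per_item=df,
        iou=float(agg["iou"]),
        miou=float(agg["miou"]),
        dsc=float(agg["dsc"]),
        aggregation=aggregation,
        per_class_iou={"foreground": float(agg["iou"]),
                       "background": float(agg["background_iou"])},
    )
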
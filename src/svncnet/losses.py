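"""Compound segmentation loss: soft Dice + binary cross-entropy.

The total loss is the convex combination

    L_total = alpha * L_Dice + (1 - alpha) * L_BCE,      alpha in [0, 1]

with alpha = 0.5 by default so both terms contribute equally. The Dice term
uses the soft (probability-valued) formulation with an additive smoothing
constant epsilon in numerator and denominator, which keeps it differentiable
and well defined on empty masks; BCE clips probabilities away from {0, 1}
for log stability.

Gradient helpers (w.r.t. the predicted probabilities) are provided for the
NumPy training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossConfig", "dice_loss", "bce_loss", "combined_loss",
           "combined_loss_and_grad"]


@dataclass
class LossConfig:
    alpha: float = 0.5
    epsilon: float = 1e-6
    probability_clip: float = 1e-7

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 < self.probability_clip < 0.5:
            raise ValueError("probability_clip must lie in (0, 0.5)")


def _as_batch(p: np.ndarray, y: np.ndarray, validate: bool):
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs reference {y.shape}")
    if validate and not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ValueError("reference mask must be binary")
    if p.ndim <= 2:  # a single image
        return p.reshape(1, -1), y.reshape(1, -1), p.shape
    return p.reshape(p.shape[0], -1), y.reshape(y.shape[0], -1), p.shape


def dice_loss(probabilities, reference, epsilon: float = 1e-6,
              validate: bool = True) -> float:
    """1 - (2*sum(p*y) + eps) / (sum(p) + sum(y) + eps), batch-averaged."""
    p, y, _ = _as_batch(probabilities, reference, validate)
    num = 2.0 * (p * y).sum(axis=1) + epsilon
    den = p.sum(axis=1) + y.sum(axis=1) + epsilon
    return float(np.mean(1.0 - num / den))


def bce_loss(probabilities, reference, probability_clip: float = 1e-7,
             validate: bool = True) -> float:
    """Pixel-mean binary cross-entropy with probability clipping."""
    p, y, _ = _as_batch(probabilities, reference, validate)
    pc = np.clip(p, probability_clip, 1.0 - probability_clip)
    return float(np.mean(-(y * np.log(pc) + (1.0 - y) * np.log1p(-pc))))


def combined_loss(probabilities, reference, config: LossConfig | None = None,
                  validate: bool = True) -> float:
    cfg = config or LossConfig()
    d = dice_loss(probabilities, reference, cfg.epsilon, validate=validate)
    b = bce_loss(probabilities, reference, cfg.probability_clip, validate=False)
    return cfg.alpha * d + (1.0 - cfg.alpha) * b


def combined_loss_and_grad(probabilities, reference,
                           config: LossConfig | None = None):
    """Loss value plus its gradient with respect to the probabilities
    (same shape as the input), for use by the training loop."""
    cfg = config or LossConfig()
    p, y, shape = _as_batch(probabilities, reference, validate=False)
    B, npix = p.shape

    num = 2.0 * (p * y).sum(axis=1, keepdims=True) + cfg.epsilon
    den = p.sum(axis=1, keepdims=True) + y.sum(axis=1, keepdims=True) + cfg.epsilon
    d_val = float(np.mean(1.0 - num / den))
    # d/dp_i of (1 - num/den) = (num - 2*y_i*den) / den^2
    d_grad = (num - 2.0 * y * den) / (den * den) / B

    pc = np.clip(p, cfg.probability_clip, 1.0 - cfg.probability_clip)
    b_val = float(np.mean(-(y * np.log(pc) + (1.0 - y) * np.log1p(-pc))))
    b_grad = (pc - y) / (pc * (1.0 - pc)) / (B * npix)

    loss = cfg.alpha * d_val + (1.0 - cfg.alpha) * b_val
    grad = (cfg.alpha * d_grad + (1.0 - cfg.alpha) * b_grad).reshape(shape)
    return loss, grad.astype(np.float32)
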
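"""Cosine annealing with warm restarts.

Within a cycle of length T_i, the learning rate at T_c epochs after the
last restart is

    eta(T_c) = eta_min + (eta_max - eta_min) / 2 * (1 + cos(pi * T_c / T_i)),

so each cycle decays from eta_max to eta_min and every cycle boundary
restarts at eta_max. The default plan is three cycles of 10, 20 and 20
epochs (50 epochs total) with eta_max = 1e-3 and eta_min = 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScheduleConfig", "lr_at", "schedule_over_training", "cycle_starts"]


@dataclass
class ScheduleConfig:
    eta_max: float = 1e-3
    eta_min: float = 1e-5
    cycle_lengths: tuple[int, ...] = (10, 20, 20)

    def __post_init__(self):
        self.cycle_lengths = tuple(int(t) for t in self.cycle_lengths)
        if self.eta_min >= self.eta_max:
            raise ValueError("eta_min must be smaller than eta_max")
        if not self.cycle_lengths or any(t <= 0 for t in self.cycle_lengths):
            raise ValueError("cycle lengths must be positive")

    @property
    def total_epochs(self) -> int:
        return sum(self.cycle_lengths)


def lr_at(Tc: float, Ti: int, config: ScheduleConfig | None = None) -> float:
    """Learning rate Tc epochs into a cycle of length Ti.

    Tc may be fractional (per-iteration stepping)."""
    cfg = config or ScheduleConfig()
    if Tc < 0 or Tc > Ti:
        raise ValueError(f"Tc must lie in [0, Ti], got Tc={Tc}, Ti={Ti}")
    return cfg.eta_min + 0.5 * (cfg.eta_max - cfg.eta_min) * (1.0 + np.cos(np.pi * Tc / Ti))


def cycle_starts(config: ScheduleConfig) -> list[int]:
    """0-based epochs at which each cycle (warm restart) begins."""
    starts, s = [], 0
    for t in config.cycle_lengths:
        starts.append(s)
        s += t
    return starts


def schedule_over_training(config: ScheduleConfig | None = None) -> np.ndarray:
    """Per-epoch learning rates over the full plan (length = total epochs).

    Epoch e in cycle i maps to Tc = e - start_i, so the first epoch of each
    cycle runs at eta_max and the last one step above eta_min."""
    cfg = config or ScheduleConfig()
    out = np.empty(cfg.total_epochs, dtype=np.float64)
    for start, Ti in zip(cycle_starts(cfg), cfg.cycle_lengths):
        for e in range(Ti):
            out[start + e] = lr_at(e, Ti, cfg)
    return out
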
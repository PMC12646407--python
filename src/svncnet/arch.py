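"""SVNC-Net: a lightweight U-shaped encoder-decoder for binary CT slice
segmentation built around depthwise-separable convolutions.

The encoder has four downsampling stages (channel widths 32/64/128/256 by
default) plus a 512-channel bottleneck whose convolutions are dilated by 2
to widen the receptive field at no parameter cost. The first encoder stage
uses standard 3x3 convolutions (depthwise filtering is ineffective on a
single input channel); from the second stage onward every double-conv block
is depthwise-separable (3x3 depthwise filter -> BN -> ReLU -> 1x1 pointwise
mix -> BN -> ReLU, MobileNet style). The decoder mirrors the encoder with
separable transposed upsampling: a depthwise 2x2 stride-2 transposed
convolution followed by a 1x1 pointwise channel reduction, then a skip
concatenation and a double-conv block of the same operator family as the
matching encoder stage. A 1x1 convolution with a sigmoid squashing produces
per-pixel foreground probabilities.

This keeps the whole network at ~1.0 million trainable parameters, roughly
a 30x reduction against a plain U-Net of the same depth.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .nn import (
    BatchNorm2d,
    Concat,
    Conv2d,
    DWConv2d,
    DWTConv2d,
    Graph,
    MaxPool2,
    PadToMatch,
    PWConv,
    ReLU,
    Sigmoid,
)

__all__ = [
    "ArchConfig", "CostSpec", "ModelSummary", "SVNCNet",
    "build_svnc_net", "count_parameters", "model_summary",
    "standard_conv_cost", "separable_conv_cost", "cost_reduction_ratio",
    "round_millions_1dp",
]


@dataclass
class ArchConfig:
    """Declarative description of the network.

    padding_mode "same" keeps every stage's spatial grid a power-of-two
    fraction of the input (bottleneck 32x32 for a 512 input);
    "valid_stage4" leaves the fourth encoder stage's conv pair unpadded,
    shrinking its grid by 4 before pooling (bottleneck 30x30 for a 512
    input) with zero-padded skip connections reconciling decoder shapes.
    Parameter counts are identical in both modes.
    """

    input_size: int = 512
    in_channels: int = 1
    stage_widths: tuple[int, ...] = (32, 64, 128, 256)
    bottleneck_width: int = 512
    bottleneck_dilation: int = 2
    separable_from_stage: int = 2
    out_channels: int = 1
    padding_mode: str = "same"

    def __post_init__(self):
        self.stage_widths = tuple(int(w) for w in self.stage_widths)
        if len(self.stage_widths) != 4:
            raise ValueError("stage_widths must list four encoder stages")
        if any(b <= a for a, b in zip(self.stage_widths, self.stage_widths[1:])):
            raise ValueError("stage_widths must be strictly increasing")
        if self.padding_mode not in ("same", "valid_stage4"):
            raise ValueError(f"unknown padding_mode {self.padding_mode!r}")
        if self.padding_mode == "same" and self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 2^4 under 'same' padding")
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if self.in_channels < 1 or self.input_size < 16:
            raise ValueError("invalid in_channels/input_size")
        if self.bottleneck_dilation < 1 or self.bottleneck_width <= self.stage_widths[-1]:
            raise ValueError("bottleneck must be wider than the last stage; dilation >= 1")
        if not (1 <= self.separable_from_stage <= 5):
            raise ValueError("separable_from_stage must be in 1..5")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_widths"] = list(self.stage_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        d = dict(d)
        if "stage_widths" in d:
            d["stage_widths"] = tuple(d["stage_widths"])
        return cls(**d)


@dataclass(frozen=True)
class CostSpec:
    """Symbols of the convolution cost model: kernel side Dk, input
    channels M, output channels N, feature-map side Df."""

    Dk: int
    M: int
    N: int
    Df: int

    def __post_init__(self):
        for name in ("Dk", "M", "N", "Df"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"CostSpec.{name} must be a strictly positive integer")


@dataclass
class ModelSummary:
    layer_table: list[dict]
    total_params: int
    params_millions_1dp: float
    nonzero_params: int


def round_millions_1dp(n: int) -> float:
    """Parameter count in millions, rounded half-up to one decimal."""
    return float((Decimal(n) / Decimal(10 ** 6)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Cost model
# ---------------------------------------------------------------------------

def standard_conv_cost(spec: CostSpec) -> int:
    """Multiply-accumulate count of a standard convolution:
    Dk^2 * M * N * Df^2 (exact integer arithmetic)."""
    return int(spec.Dk) ** 2 * int(spec.M) * int(spec.N) * int(spec.Df) ** 2


def separable_conv_cost(spec: CostSpec) -> int:
    """MAC count of a depthwise-separable convolution: the depthwise
    filtering term Dk^2*M*Df^2 plus the pointwise combination M*N*Df^2."""
    Dk, M, N, Df = int(spec.Dk), int(spec.M), int(spec.N), int(spec.Df)
    return Dk ** 2 * M * Df ** 2 + M * N * Df ** 2


def cost_reduction_ratio(Dk: int, N: int) -> float:
    """separable/standard cost ratio 1/N + 1/Dk^2 (independent of M, Df)."""
    if Dk < 1 or N < 1:
        raise ValueError("Dk and N must be >= 1")
    return 1.0 / N + 1.0 / (Dk * Dk)


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

class SVNCNet:
    """The built network: a Graph plus its configuration."""

    def __init__(self, config: ArchConfig, seed: int = 0):
        self.config = config
        self.graph, self.skip_names, self.head_name = _build_graph(config, seed)

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.graph.forward(x, training=training)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel foreground probabilities in [0, 1] (evaluation mode)."""
        return self.graph.forward(x, training=False)

    def parameters(self):
        return self.graph.parameters()

    def state_dict(self):
        return self.graph.state_dict()

    def load_state_dict(self, state):
        self.graph.load_state_dict(state)


def _sep_block(g, rng, prefix, inp, in_c, out_c, dilation=1, padding="same"):
    n = g.add(DWConv2d(f"{prefix}.dw", inp, in_c, k=3, dilation=dilation,
                       padding=padding, rng=rng))
    n = g.add(BatchNorm2d(f"{prefix}.dw_bn", n, in_c))
    n = g.add(ReLU(f"{prefix}.dw_relu", [n]))
    n = g.add(PWConv(f"{prefix}.pw", n, in_c, out_c, rng=rng))
    n = g.add(BatchNorm2d(f"{prefix}.pw_bn", n, out_c))
    n = g.add(ReLU(f"{prefix}.pw_relu", [n]))
    return n


def _std_block(g, rng, prefix, inp, in_c, out_c, padding="same"):
    n = g.add(Conv2d(f"{prefix}.conv", inp, in_c, out_c, k=3, padding=padding, rng=rng))
    n = g.add(BatchNorm2d(f"{prefix}.bn", n, out_c))
    n = g.add(ReLU(f"{prefix}.relu", [n]))
    return n


def _double(g, rng, prefix, inp, in_c, out_c, separable, dilation=1, padding="same"):
    block = _sep_block if separable else _std_block
    kw = {"dilation": dilation} if separable else {}
    n = block(g, rng, f"{prefix}a", inp, in_c, out_c, padding=padding, **kw)
    n = block(g, rng, f"{prefix}b", n, out_c, out_c, padding=padding, **kw)
    return n


def _up_block(g, rng, prefix, inp, in_c, out_c):
    # separable transposed upsampling: depthwise 2x2 stride-2, then 1x1 mix
    n = g.add(DWTConv2d(f"{prefix}.up_dw", inp, in_c, rng=rng))
    n = g.add(BatchNorm2d(f"{prefix}.up_dw_bn", n, in_c))
    n = g.add(ReLU(f"{prefix}.up_dw_relu", [n]))
    n = g.add(PWConv(f"{prefix}.up_pw", n, in_c, out_c, rng=rng))
    n = g.add(BatchNorm2d(f"{prefix}.up_pw_bn", n, out_c))
    n = g.add(ReLU(f"{prefix}.up_pw_relu", [n]))
    return n


def _build_graph(cfg: ArchConfig, seed: int):
    rng = np.random.default_rng(seed)
    g = Graph(cfg.in_channels)
    widths = cfg.stage_widths

    skips = []
    n, c = "input", cfg.in_channels
    for s, w in enumerate(widths, start=1):
        sep = s >= cfg.separable_from_stage
        pad = "valid" if (cfg.padding_mode == "valid_stage4" and s == 4) else "same"
        n = _double(g, rng, f"enc{s}", n, c, w, separable=sep, padding=pad)
        skips.append((n, w))
        n = g.add(MaxPool2(f"enc{s}.pool", [n]))
        c = w

    n = _double(g, rng, "bottleneck", n, c, cfg.bottleneck_width,
                separable=True, dilation=cfg.bottleneck_dilation)
    c = cfg.bottleneck_width

    for s in range(4, 0, -1):
        skip_name, skip_c = skips[s - 1]
        w = widths[s - 1]
        n = _up_block(g, rng, f"dec{s}", n, c, w)
        n = g.add(PadToMatch(f"dec{s}.pad", [n, skip_name]))
        n = g.add(Concat(f"dec{s}.cat", [n, skip_name]))
        sep = s >= cfg.separable_from_stage
        n = _double(g, rng, f"dec{s}", n, w + skip_c, w, separable=sep)
        c = w

    head = g.add(PWConv("head.conv", n, c, cfg.out_channels, bias=True, rng=rng))
    g.add(Sigmoid("head.sigmoid", [head]))
    return g, [s for s, _ in skips], "head.conv"


def build_svnc_net(config: ArchConfig | None = None, seed: int = 0) -> SVNCNet:
    """Construct the network from a declarative configuration.

    The returned model maps (B, in_channels, H, W) image batches to
    (B, out_channels, H, W) per-pixel probabilities in [0, 1].
    """
    return SVNCNet(config or ArchConfig(), seed=seed)


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

def count_parameters(model) -> ModelSummary:
    """Exact trainable-scalar count (conv kernels, biases, BN affine)."""
    summary = model_summary(model)
    return summary


def model_summary(model) -> ModelSummary:
    """Layer table (forward order, with output channels and spatial sizes
    propagated from config.input_size) plus parameter totals."""
    g = model.graph if hasattr(model, "graph") else model
    size = model.config.input_size if hasattr(model, "config") else None
    ch = g.infer_channels()
    hw = g.infer_hw((size, size)) if size else None
    table = []
    total = 0
    nonzero = 0
    for node in g.nodes:
        nparams = sum(p.size for p in node.parameters())
        total += nparams
        nonzero += sum(p.nonzero for p in node.parameters())
        row = {
            "name": node.name,
            "kind": node.kind,
            "in_channels": ch[node.inputs[0]],
            "out_channels": ch[node.name],
            "params": nparams,
        }
        if hw is not None:
            row["out_h"], row["out_w"] = hw[node.name]
        table.append(row)
    return ModelSummary(
        layer_table=table,
        total_params=total,
        params_millions_1dp=round_millions_1dp(total),
        nonzero_params=nonzero,
    )
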
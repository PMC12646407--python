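"""Post-training model compression: magnitude weight pruning, structural
filter pruning, and emulated 8-bit post-training quantization.

Weight pruning zeroes the globally smallest 15% (by default) of
convolutional and transposed-convolutional kernel weights by absolute
magnitude, with no fine-tuning afterwards; batch-norm parameters and biases
stay untouched. A sparsity mask is retained on every pruned tensor so
nonzero accounting is exact.

Filter pruning removes, per channel-producing convolution, the fraction of
output filters with the smallest L1 kernel norm, then propagates the
removals through depthwise convolutions, batch norm and skip-connection
concatenations so the network's input/output shape contract is preserved.

Quantization folds batch norm into the preceding convolutions, stores each
weight tensor as int8 with a symmetric per-tensor scale, and calibrates
asymmetric per-tensor activation ranges from representative inputs;
execution is emulated (dequantized weights, fake-quantized activations),
the contract being storage (about a quarter of the float payload) and
numerics (dequantized weights within half a quantization step).
"""

from __future__ import annotations

import copy
import io
import json
import time
from dataclasses import dataclass, field

import numpy as np

from .arch import round_millions_1dp
from .nn.graph import Graph, INPUT, Parameter
from .nn.ops import BatchNorm2d, Concat, Conv2d, DWConv2d, DWTConv2d

__all__ = [
    "PruneConfig", "QuantConfig", "CompressionReport", "QuantizedModel",
    "magnitude_weight_prune", "filter_prune", "fold_batchnorm",
    "quantize_int8", "compression_report", "serialized_size",
]

_CONV_TYPES = (Conv2d, DWConv2d, DWTConv2d)  # PWConv subclasses Conv2d


@dataclass
class PruneConfig:
    weight_fraction: float = 0.15
    filter_fraction: float = 0.20
    strategy: str = "W"  # "W" (weights only) or "W+F" (weights + filters)
    per_layer: bool = False  # rank magnitudes within each tensor instead of globally

    def __post_init__(self):
        if not 0.0 <= self.weight_fraction < 1.0:
            raise ValueError("weight_fraction must lie in [0, 1)")
        if not 0.0 <= self.filter_fraction < 1.0:
            raise ValueError("filter_fraction must lie in [0, 1)")
        if self.strategy not in ("W", "W+F"):
            raise ValueError("strategy must be 'W' or 'W+F'")


@dataclass
class QuantConfig:
    bit_width: int = 8
    weight_scheme: str = "symmetric_per_tensor"
    activation_scheme: str = "asymmetric_per_tensor"
    calibration_batches: int = 1

    def __post_init__(self):
        if self.bit_width != 8:
            raise ValueError("only 8-bit quantization is supported")


@dataclass
class CompressionReport:
    nonzero_params: int
    total_params: int
    params_millions_1dp: float
    serialized_bytes: int
    mean_latency_ms: float  # informational; hardware-dependent
    metric_delta: float | None = None
    notes: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _graph_of(model) -> Graph:
    return model.graph if hasattr(model, "graph") else model


def _prunable_weights(g: Graph):
    """Kernel weight Parameters of conv/transposed-conv nodes, in
    declaration order (biases and batch norm excluded)."""
    return [n.W for n in g.nodes if isinstance(n, _CONV_TYPES)]


# ---------------------------------------------------------------------------
# Magnitude weight pruning
# ---------------------------------------------------------------------------

def magnitude_weight_prune(model, config: PruneConfig | None = None):
    """Zero the floor(weight_fraction * P) globally smallest-|w| in-scope
    weights (ties broken by flattened declaration order). Returns a pruned
    copy; no fine-tuning is performed."""
    cfg = config or PruneConfig()
    pruned = copy.deepcopy(model)
    g = _graph_of(pruned)
    weights = _prunable_weights(g)
    if cfg.weight_fraction == 0.0 or not weights:
        return pruned

    if cfg.per_layer:
        for p in weights:
            k = int(np.floor(cfg.weight_fraction * p.size))
            if k == 0:
                continue
            flat = np.abs(p.data.ravel())
            drop = np.argsort(flat, kind="stable")[:k]
            mask = np.ones(p.size, dtype=bool)
            mask[drop] = False
            p.mask = mask.reshape(p.data.shape)
            p.data = p.data * p.mask
        return pruned

    sizes = [p.size for p in weights]
    total = int(np.sum(sizes))
    k = int(np.floor(cfg.weight_fraction * total))
    if k == 0:
        return pruned
    flat = np.concatenate([np.abs(p.data.ravel()) for p in weights])
    drop = np.argsort(flat, kind="stable")[:k]
    keep_mask = np.ones(total, dtype=bool)
    keep_mask[drop] = False
    offset = 0
    for p, sz in zip(weights, sizes):
        m = keep_mask[offset:offset + sz].reshape(p.data.shape)
        p.mask = m
        p.data = p.data * m
        offset += sz
    return pruned


# ---------------------------------------------------------------------------
# Structural filter pruning
# ---------------------------------------------------------------------------

def filter_prune(model, config: PruneConfig | None = None):
    """Remove the floor(filter_fraction * F) output filters with smallest
    L1 kernel norm from every channel-producing convolution (except the
    output head), propagating channel removals through depthwise layers,
    batch norm and concatenating skip connections. Returns a structurally
    reduced copy whose forward shape contract is unchanged."""
    cfg = config or PruneConfig()
    pruned = copy.deepcopy(model)
    g = _graph_of(pruned)
    head = getattr(pruned, "head_name", None)
    if head is None:  # bare Graph: treat the last parametered conv as head
        convs = [n for n in g.nodes if isinstance(n, _CONV_TYPES)]
        head = convs[-1].name if convs else None

    orig_ch = g.infer_channels()
    f = cfg.filter_fraction
    # keep[name]: surviving channel indices, in the node's ORIGINAL output
    # channel coordinate system
    keep: dict[str, np.ndarray] = {INPUT: np.arange(g.in_channels)}

    for n in g.nodes:
        kin = [keep[i] for i in n.inputs]
        if isinstance(n, (Conv2d,)):  # includes PWConv
            n.W.data = np.ascontiguousarray(n.W.data[:, kin[0]])
            n.in_c = len(kin[0])
            if f > 0.0 and n.name != head:
                F = n.out_c
                r = int(np.floor(f * F))
                if F - r < 1:
                    raise ValueError(f"filter pruning would empty layer {n.name}")
                if r > 0:
                    scores = np.abs(n.W.data).reshape(F, -1).sum(axis=1)
                    drop = set(np.argsort(scores, kind="stable")[:r].tolist())
                    kept = np.array([i for i in range(F) if i not in drop])
                    n.W.data = np.ascontiguousarray(n.W.data[kept])
                    if n.b is not None:
                        n.b.data = np.ascontiguousarray(n.b.data[kept])
                    n.out_c = len(kept)
                    keep[n.name] = kept
                else:
                    keep[n.name] = np.arange(F)
            else:
                keep[n.name] = np.arange(n.out_c)
        elif isinstance(n, (DWConv2d, DWTConv2d)):
            n.W.data = np.ascontiguousarray(n.W.data[kin[0]])
            if n.b is not None:
                n.b.data = np.ascontiguousarray(n.b.data[kin[0]])
            n.channels = len(kin[0])
            keep[n.name] = kin[0]
        elif isinstance(n, BatchNorm2d):
            idx = kin[0]
            n.gamma.data = np.ascontiguousarray(n.gamma.data[idx])
            n.beta.data = np.ascontiguousarray(n.beta.data[idx])
            n.running_mean = np.ascontiguousarray(n.running_mean[idx])
            n.running_var = np.ascontiguousarray(n.running_var[idx])
            n.channels = len(idx)
            keep[n.name] = idx
        elif isinstance(n, Concat):
            c0 = orig_ch[n.inputs[0]]
            keep[n.name] = np.concatenate([kin[0], c0 + kin[1]])
        else:  # relu, sigmoid, pool, pad: channel pass-through
            keep[n.name] = kin[0]

    for p in g.parameters():
        p.grad = None
        p.mask = None
    return pruned


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

def fold_batchnorm(model):
    """Fold every batch norm into its preceding convolution (using the
    running statistics), removing the BN nodes. The convolution gains a
    bias. Returns a folded copy."""
    folded = copy.deepcopy(model)
    g = _graph_of(folded)

    consumers: dict[str, list[str]] = {}
    for n in g.nodes:
        for i in n.inputs:
            consumers.setdefault(i, []).append(n.name)

    rename: dict[str, str] = {}
    new_nodes = []
    for n in g.nodes:
        n.inputs = [rename.get(i, i) for i in n.inputs]
        if isinstance(n, BatchNorm2d):
            src = g.by_name.get(n.inputs[0])
            if (isinstance(src, _CONV_TYPES)
                    and consumers.get(src.name, []) == [n.name]):
                s = (n.gamma.data / np.sqrt(n.running_var + n.eps)).astype(np.float32)
                src.W.data = src.W.data * s.reshape((-1,) + (1,) * (src.W.data.ndim - 1))
                old_b = src.b.data if src.b is not None else 0.0
                bias = (n.beta.data - n.running_mean * s + old_b * s).astype(np.float32)
                src.b = Parameter(f"{src.name}.bias", bias)
                rename[n.name] = src.name
                del g.by_name[n.name]
                continue
        new_nodes.append(n)
    g.nodes = new_nodes
    return folded


class QuantizedModel:
    """Emulated int8 model: folded graph, int8 weight payloads with
    per-tensor scales, and calibrated activation ranges applied as
    fake-quantization during the forward pass."""

    def __init__(self, model, qweights: dict, act_ranges: dict,
                 config: QuantConfig):
        self._model = model  # BN-folded, weights already dequantized in place
        self.qweights = qweights  # name -> (int8 array, float scale)
        self.act_ranges = act_ranges  # node name -> (min, max)
        self.config = config

    @property
    def graph(self) -> Graph:
        return _graph_of(self._model)

    @property
    def config_arch(self):
        return getattr(self._model, "config", None)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.graph.forward(x, training=False, act_quant=self.act_ranges)

    __call__ = predict_proba

    def parameters(self):
        return self.graph.parameters()

    def weight_payload_bytes(self) -> int:
        """Raw bytes of the quantized kernel payloads (int8 data plus one
        float32 scale and int32 zero-point per tensor)."""
        return sum(q.nbytes + 8 for q, _ in self.qweights.values())

    def float_weight_payload_bytes(self) -> int:
        """Raw float32 bytes of the same kernel tensors before quantization."""
        return sum(q.size * 4 for q, _ in self.qweights.values())

    def serialized_payload(self) -> bytes:
        """int8 weight payloads + scales + remaining float tensors."""
        buf = io.BytesIO()
        arrays = {}
        for name, (q, scale) in self.qweights.items():
            arrays[f"q:{name}"] = q
            arrays[f"scale:{name}"] = np.float32(scale)
        for p in self.graph.parameters():
            if p.name not in self.qweights:
                arrays[f"f:{p.name}"] = p.data
        np.savez(buf, **arrays)
        return buf.getvalue()


def quantize_int8(model, calibration_inputs, config: QuantConfig | None = None
                  ) -> QuantizedModel:
    """Post-training quantization without retraining.

    calibration_inputs: iterable of (B, C, H, W) batches used to record
    per-node activation ranges on the BN-folded model.
    """
    cfg = config or QuantConfig()
    batches = list(calibration_inputs)
    if not batches:
        raise ValueError("calibration set must contain at least one batch")

    folded = fold_batchnorm(model)
    g = _graph_of(folded)

    ranges: dict = {}
    for batch in batches:
        g.forward(np.asarray(batch, dtype=np.float32), training=False,
                  record_ranges=ranges)

    qweights: dict = {}
    for p in [n.W for n in g.nodes if isinstance(n, _CONV_TYPES)]:
        amax = float(np.abs(p.data).max())
        scale = amax / 127.0 if amax > 0 else 1.0
        q = np.clip(np.round(p.data / scale), -127, 127).astype(np.int8)
        qweights[p.name] = (q, scale)
        p.data = (q.astype(np.float32) * scale)

    return QuantizedModel(folded, qweights, dict(ranges), cfg)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def serialized_size(model) -> int:
    """Bytes of the serialized parameter state."""
    if isinstance(model, QuantizedModel):
        return len(model.serialized_payload())
    buf = io.BytesIO()
    np.savez(buf, **_graph_of(model).state_dict())
    return len(buf.getvalue())


def compression_report(model, eval_pairs=None, baseline=None,
                       input_hw: tuple[int, int] = (64, 64),
                       latency_reps: int = 3) -> CompressionReport:
    """Parameter/size accounting for an original, pruned or quantized model.

    eval_pairs: optional sequence of (image, reference mask) 2D arrays; the
    report then carries the mean-IoU change of `model` against `baseline`
    on those pairs. Latency is informational only (hardware-dependent).
    """
    from .metrics import MaskPair, binarize, iou as _iou

    g = _graph_of(model)
    params = g.parameters()
    nonzero = sum(p.nonzero for p in params)
    total = sum(p.size for p in params)

    x = np.zeros((1, g.in_channels, *input_hw), dtype=np.float32)
    fwd = model.predict_proba if hasattr(model, "predict_proba") else (
        lambda a: g.forward(a, training=False))
    fwd(x)  # warm-up
    t0 = time.perf_counter()
    for _ in range(latency_reps):
        fwd(x)
    latency = (time.perf_counter() - t0) / latency_reps * 1e3

    delta = None
    if eval_pairs is not None and baseline is not None:
        base_fwd = baseline.predict_proba if hasattr(baseline, "predict_proba") else (
            lambda a: _graph_of(baseline).forward(a, training=False))
        vals, base_vals = [], []
        for img, ref in eval_pairs:
            xb = np.asarray(img, dtype=np.float32)[None, None]
            vals.append(_iou(MaskPair(binarize(fwd(xb)[0, 0]), ref)))
            base_vals.append(_iou(MaskPair(binarize(base_fwd(xb)[0, 0]), ref)))
        delta = float(np.mean(vals) - np.mean(base_vals))

    return CompressionReport(
        nonzero_params=nonzero,
        total_params=total,
        params_millions_1dp=round_millions_1dp(nonzero),
        serialized_bytes=serialized_size(model),
        mean_latency_ms=latency,
        metric_delta=delta,
        notes={"latency": "hardware-dependent, informational only"},
    )
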
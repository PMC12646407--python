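"""Minimal static-graph neural-network engine on NumPy.

The segmentation network is expressed as a flat, topologically ordered list
of nodes (convolutions, batch norm, pooling, concatenation, ...). Each node
implements forward and reverse-mode backward passes and declares how channel
counts and spatial sizes propagate, which the architecture summary and the
structural (filter) pruning machinery rely on.

Arrays are float32 with layout (batch, channels, height, width).
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient and an optional
    sparsity mask (set by magnitude pruning; kept so nonzero accounting
    stays exact)."""

    __slots__ = ("name", "data", "grad", "mask")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.mask: np.ndarray | None = None

    @property
    def size(self) -> int:
        return int(self.data.size)

    @property
    def nonzero(self) -> int:
        """Count of scalars not removed by pruning: masked entries count as
        zero; unmasked tensors count in full (a trainable scalar that
        happens to sit at 0.0, e.g. a freshly initialized bias, is still a
        parameter)."""
        if self.mask is not None:
            return int(self.mask.sum())
        return int(self.data.size)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter({self.name}, shape={self.data.shape})"


class Node:
    """Base class for graph operations."""

    kind = "node"

    def __init__(self, name: str, inputs: list[str]):
        self.name = name
        self.inputs = list(inputs)

    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, xs, ctx, training):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g, ctx):  # pragma: no cover - abstract
        raise NotImplementedError

    def out_channels(self, in_channels: list[int]) -> int:
        return in_channels[0]

    def out_hw(self, in_hw: list[tuple[int, int]]) -> tuple[int, int]:
        return in_hw[0]


INPUT = "input"


def _fake_quant(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Emulate asymmetric per-tensor uint8 quantization of an activation."""
    if hi <= lo:
        return x
    scale = (hi - lo) / 255.0
    q = np.clip(np.round((x - lo) / scale), 0, 255)
    return (q * scale + lo).astype(np.float32)


class Graph:
    """Topologically ordered DAG; the last node is the output."""

    def __init__(self, in_channels: int):
        self.in_channels = in_channels
        self.nodes: list[Node] = []
        self.by_name: dict[str, Node] = {INPUT: None}
        self._vals: dict[str, np.ndarray] | None = None
        self._ctx: dict | None = None

    def add(self, node: Node) -> str:
        if node.name in self.by_name:
            raise ValueError(f"duplicate node name {node.name!r}")
        for i in node.inputs:
            if i not in self.by_name:
                raise ValueError(f"node {node.name!r} references unknown input {i!r}")
        self.nodes.append(node)
        self.by_name[node.name] = node
        return node.name

    # ------------------------------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        record_ranges: dict | None = None,
        act_quant: dict | None = None,
    ) -> np.ndarray:
        """Run the graph on a (B, C, H, W) batch.

        record_ranges, if given, accumulates per-node activation min/max
        (used for quantization calibration); act_quant, if given, maps node
        names to (min, max) ranges and fake-quantizes every activation
        (emulated int8 execution).
        """
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected input of shape (B, {self.in_channels}, H, W), got {x.shape}"
            )
        vals: dict[str, np.ndarray] = {INPUT: x}
        ctx: dict = {}
        for n in self.nodes:
            out = n.forward([vals[i] for i in n.inputs], ctx, training)
            if record_ranges is not None:
                lo, hi = record_ranges.get(n.name, (np.inf, -np.inf))
                record_ranges[n.name] = (min(lo, float(out.min())), max(hi, float(out.max())))
            if act_quant is not None and n.name in act_quant:
                out = _fake_quant(out, *act_quant[n.name])
            vals[n.name] = out
        if training:
            self._vals, self._ctx = vals, ctx
        else:
            self._vals = self._ctx = None
        return vals[self.nodes[-1].name]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate from the graph output; returns grad w.r.t. input.

        Must follow a forward(..., training=True) call."""
        if self._ctx is None:
            raise RuntimeError("backward() requires a preceding training-mode forward()")
        grads: dict[str, np.ndarray] = {self.nodes[-1].name: np.asarray(dy, dtype=np.float32)}
        for n in reversed(self.nodes):
            g = grads.pop(n.name, None)
            if g is None:
                continue
            gins = n.backward(g, self._ctx)
            for iname, gi in zip(n.inputs, gins):
                if gi is None:
                    continue
                if iname in grads:
                    grads[iname] = grads[iname] + gi
                else:
                    grads[iname] = gi
        self._vals = self._ctx = None
        return grads.get(INPUT, None)

    # ------------------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for n in self.nodes:
            out.extend(n.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for n in self.nodes:
            for p in n.parameters():
                state[f"param:{p.name}"] = p.data
            for key, buf in n.buffers().items():
                state[f"buffer:{n.name}:{key}"] = buf
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n in self.nodes:
            for p in n.parameters():
                key = f"param:{p.name}"
                if key not in state:
                    raise KeyError(f"missing parameter {key!r} in state")
                if state[key].shape != p.data.shape:
                    raise ValueError(f"shape mismatch for {key!r}")
                p.data = np.ascontiguousarray(state[key], dtype=np.float32)
            bufs = n.buffers()
            for key in bufs:
                skey = f"buffer:{n.name}:{key}"
                if skey in state:
                    bufs[key][...] = state[skey]

    # ------------------------------------------------------------------
    def infer_channels(self) -> dict[str, int]:
        ch = {INPUT: self.in_channels}
        for n in self.nodes:
            ch[n.name] = n.out_channels([ch[i] for i in n.inputs])
        return ch

    def infer_hw(self, input_hw: tuple[int, int]) -> dict[str, tuple[int, int]]:
        hw = {INPUT: tuple(input_hw)}
        for n in self.nodes:
            hw[n.name] = n.out_hw([hw[i] for i in n.inputs])
        return hw
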
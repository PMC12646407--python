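"""Graph operations: convolutions, batch norm, pooling, activations.

Convolutions are implemented as kernel-tap sums of BLAS channel mixes
(tensordot), which is fast enough on CPU for the 3x3 kernels used here and
keeps the backward passes simple and exact.
"""

from __future__ import annotations

import numpy as np

from .graph import Node, Parameter


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


class Conv2d(Node):
    """Standard 2D convolution (no groups), square kernel, stride 1.

    padding "same" keeps the spatial size (requires odd effective kernel);
    "valid" shrinks it by dilation*(k-1).
    """

    kind = "conv"

    def __init__(self, name, inp, in_c, out_c, k=3, dilation=1, padding="same",
                 bias=False, rng=None):
        super().__init__(name, [inp])
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.in_c, self.out_c, self.k, self.dilation = in_c, out_c, k, dilation
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        self.W = Parameter(f"{name}.weight", _he_init(rng, (out_c, in_c, k, k), k * k * in_c))
        self.b = Parameter(f"{name}.bias", np.zeros(out_c)) if bias else None

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    @property
    def _pad(self) -> int:
        return self.dilation * (self.k - 1) // 2 if self.padding == "same" else 0

    def forward(self, xs, ctx, training):
        x = xs[0]
        d, k = self.dilation, self.k
        xp = _pad_hw(x, self._pad)
        Ho = xp.shape[2] - d * (k - 1)
        Wo = xp.shape[3] - d * (k - 1)
        if Ho < 1 or Wo < 1:
            raise ValueError(f"{self.name}: input too small for valid convolution")
        out = np.zeros((x.shape[0], self.out_c, Ho, Wo), dtype=np.float32)
        W = self.W.data
        for ki in range(k):
            for kj in range(k):
                xsl = xp[:, :, ki * d:ki * d + Ho, kj * d:kj * d + Wo]
                out += np.tensordot(xsl, W[:, :, ki, kj], axes=([1], [1])).transpose(0, 3, 1, 2)
        if self.b is not None:
            out += self.b.data[None, :, None, None]
        if training:
            ctx[self.name] = (xp, x.shape, Ho, Wo)
        return out

    def backward(self, g, ctx):
        xp, xshape, Ho, Wo = ctx[self.name]
        d, k = self.dilation, self.k
        W = self.W.data
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                xsl = xp[:, :, ki * d:ki * d + Ho, kj * d:kj * d + Wo]
                dW[:, :, ki, kj] = np.tensordot(g, xsl, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, ki * d:ki * d + Ho, kj * d:kj * d + Wo] += np.tensordot(
                    g, W[:, :, ki, kj], axes=([1], [0])).transpose(0, 3, 1, 2)
        self.W.accumulate(dW)
        if self.b is not None:
            self.b.accumulate(g.sum(axis=(0, 2, 3)))
        p = self._pad
        dx = dxp if p == 0 else dxp[:, :, p:-p, p:-p]
        return [dx]

    def out_channels(self, in_channels):
        return self.out_c

    def out_hw(self, in_hw):
        h, w = in_hw[0]
        if self.padding == "same":
            return (h, w)
        s = self.dilation * (self.k - 1)
        return (h - s, w - s)


class PWConv(Conv2d):
    """1x1 pointwise convolution (channel mix)."""

    kind = "pwconv"

    def __init__(self, name, inp, in_c, out_c, bias=False, rng=None):
        super().__init__(name, inp, in_c, out_c, k=1, dilation=1, padding="same",
                         bias=bias, rng=rng)


class DWConv2d(Node):
    """Depthwise 2D convolution: one k x k spatial filter per channel."""

    kind = "dwconv"

    def __init__(self, name, inp, channels, k=3, dilation=1, padding="same",
                 bias=False, rng=None):
        super().__init__(name, [inp])
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.channels, self.k, self.dilation, self.padding = channels, k, dilation, padding
        rng = rng or np.random.default_rng(0)
        self.W = Parameter(f"{name}.weight", _he_init(rng, (channels, k, k), k * k))
        self.b = Parameter(f"{name}.bias", np.zeros(channels)) if bias else None

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    @property
    def _pad(self) -> int:
        return self.dilation * (self.k - 1) // 2 if self.padding == "same" else 0

    def forward(self, xs, ctx, training):
        x = xs[0]
        d, k = self.dilation, self.k
        xp = _pad_hw(x, self._pad)
        Ho = xp.shape[2] - d * (k - 1)
        Wo = xp.shape[3] - d * (k - 1)
        if Ho < 1 or Wo < 1:
            raise ValueError(f"{self.name}: input too small for valid convolution")
        out = np.zeros((x.shape[0], self.channels, Ho, Wo), dtype=np.float32)
        W = self.W.data
        for ki in range(k):
            for kj in range(k):
                out += xp[:, :, ki * d:ki * d + Ho, kj * d:kj * d + Wo] * W[None, :, ki, kj, None, None]
        if self.b is not None:
            out += self.b.data[None, :, None, None]
        if training:
            ctx[self.name] = (xp, Ho, Wo)
        return out

    def backward(self, g, ctx):
        xp, Ho, Wo = ctx[self.name]
        d, k = self.dilation, self.k
        W = self.W.data
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                xsl = xp[:, :, ki * d:ki * d + Ho, kj * d:kj * d + Wo]
                dW[:, ki, kj] = (g * xsl).sum(axis=(0, 2, 3))
                dxp[:, :, ki * d:ki * d + Ho, kj * d:kj * d + Wo] += g * W[None, :, ki, kj, None, None]
        self.W.accumulate(dW)
        if self.b is not None:
            self.b.accumulate(g.sum(axis=(0, 2, 3)))
        p = self._pad
        dx = dxp if p == 0 else dxp[:, :, p:-p, p:-p]
        return [dx]

    def out_channels(self, in_channels):
        return self.channels

    def out_hw(self, in_hw):
        h, w = in_hw[0]
        if self.padding == "same":
            return (h, w)
        s = self.dilation * (self.k - 1)
        return (h - s, w - s)


class DWTConv2d(Node):
    """Depthwise transposed convolution, kernel 2, stride 2 (doubles H, W)."""

    kind = "dwtconv"

    def __init__(self, name, inp, channels, bias=False, rng=None):
        super().__init__(name, [inp])
        self.channels = channels
        self.k = 2
        rng = rng or np.random.default_rng(0)
        self.W = Parameter(f"{name}.weight", _he_init(rng, (channels, 2, 2), 4))
        self.b = Parameter(f"{name}.bias", np.zeros(channels)) if bias else None

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, xs, ctx, training):
        x = xs[0]
        B, C, H, W_ = x.shape
        out = np.empty((B, C, 2 * H, 2 * W_), dtype=np.float32)
        for di in range(2):
            for dj in range(2):
                out[:, :, di::2, dj::2] = x * self.W.data[None, :, di, dj, None, None]
        if self.b is not None:
            out += self.b.data[None, :, None, None]
        if training:
            ctx[self.name] = x
        return out

    def backward(self, g, ctx):
        x = ctx[self.name]
        dW = np.zeros_like(self.W.data)
        dx = np.zeros_like(x)
        for di in range(2):
            for dj in range(2):
                gsl = g[:, :, di::2, dj::2]
                dW[:, di, dj] = (gsl * x).sum(axis=(0, 2, 3))
                dx += gsl * self.W.data[None, :, di, dj, None, None]
        self.W.accumulate(dW)
        if self.b is not None:
            self.b.accumulate(g.sum(axis=(0, 2, 3)))
        return [dx]

    def out_channels(self, in_channels):
        return self.channels

    def out_hw(self, in_hw):
        h, w = in_hw[0]
        return (2 * h, 2 * w)


class BatchNorm2d(Node):
    """Per-channel batch normalization with learnable affine parameters.

    Training uses batch statistics and updates exponential running averages;
    evaluation uses the running averages.
    """

    kind = "bn"

    def __init__(self, name, inp, channels, eps=1e-5, momentum=0.1):
        super().__init__(name, [inp])
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def parameters(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, xs, ctx, training):
        x = xs[0]
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if training:
            ctx[self.name] = (xhat, inv, x.shape)
        return (self.gamma.data[None, :, None, None] * xhat
                + self.beta.data[None, :, None, None]).astype(np.float32)

    def backward(self, g, ctx):
        xhat, inv, xshape = ctx[self.name]
        m = xshape[0] * xshape[2] * xshape[3]
        sum_g = g.sum(axis=(0, 2, 3))
        sum_gx = (g * xhat).sum(axis=(0, 2, 3))
        self.gamma.accumulate(sum_gx)
        self.beta.accumulate(sum_g)
        coef = (self.gamma.data * inv / m)[None, :, None, None]
        dx = coef * (m * g - sum_g[None, :, None, None] - xhat * sum_gx[None, :, None, None])
        return [dx.astype(np.float32)]


class ReLU(Node):
    kind = "relu"

    def forward(self, xs, ctx, training):
        x = xs[0]
        out = np.maximum(x, 0.0)
        if training:
            ctx[self.name] = x > 0
        return out

    def backward(self, g, ctx):
        return [g * ctx[self.name]]


class Sigmoid(Node):
    kind = "sigmoid"

    def forward(self, xs, ctx, training):
        x = np.clip(xs[0], -60.0, 60.0)
        y = 1.0 / (1.0 + np.exp(-x))
        if training:
            ctx[self.name] = y
        return y.astype(np.float32)

    def backward(self, g, ctx):
        y = ctx[self.name]
        return [g * y * (1.0 - y)]


class MaxPool2(Node):
    """2x2 max pooling with stride 2 (even spatial sizes required)."""

    kind = "pool"

    def forward(self, xs, ctx, training):
        x = xs[0]
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"{self.name}: spatial size {H}x{W} not divisible by 2")
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(B, C, H // 2, W // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            ctx[self.name] = (idx, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, g, ctx):
        idx, xshape = ctx[self.name]
        B, C, H, W = xshape
        dxr = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
        return [np.ascontiguousarray(dx)]

    def out_hw(self, in_hw):
        h, w = in_hw[0]
        return (h // 2, w // 2)


class Concat(Node):
    """Channel-wise concatenation of two feature maps of equal spatial size."""

    kind = "concat"

    def forward(self, xs, ctx, training):
        a, b = xs
        if a.shape[2:] != b.shape[2:]:
            raise ValueError(
                f"{self.name}: spatial mismatch {a.shape[2:]} vs {b.shape[2:]} "
                "(skip-connection padding failed to reconcile shapes)")
        if training:
            ctx[self.name] = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, g, ctx):
        ca = ctx[self.name]
        return [g[:, :ca], g[:, ca:]]

    def out_channels(self, in_channels):
        return in_channels[0] + in_channels[1]

    def out_hw(self, in_hw):
        return in_hw[1]


class PadToMatch(Node):
    """Zero-pad the first input spatially so it matches the second input.

    Used on decoder feature maps before concatenation with an encoder skip
    when unpadded encoder convolutions have shrunk the spatial grid.
    """

    kind = "pad"

    def forward(self, xs, ctx, training):
        x, ref = xs
        dh = ref.shape[2] - x.shape[2]
        dw = ref.shape[3] - x.shape[3]
        if dh < 0 or dw < 0:
            raise ValueError(f"{self.name}: cannot pad {x.shape} down to {ref.shape}")
        pads = ((0, 0), (0, 0), (dh // 2, dh - dh // 2), (dw // 2, dw - dw // 2))
        if training:
            ctx[self.name] = (pads, x.shape)
        return np.pad(x, pads) if (dh or dw) else x

    def backward(self, g, ctx):
        pads, xshape = ctx[self.name]
        (_, _), (_, _), (t, b), (l, r) = pads
        h, w = xshape[2], xshape[3]
        return [g[:, :, t:t + h, l:l + w], None]

    def out_channels(self, in_channels):
        return in_channels[0]

    def out_hw(self, in_hw):
        return in_hw[1]
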
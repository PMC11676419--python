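"""Neural layers on NHWC feature maps and (batch, tokens, dim) sequences.

Convolutions use "same" padding computed the conventional way for strided
kernels (total padding ``(out-1)*stride + eff_k - in``, extra pixel on the
bottom/right), so a 3x3 stride-2 conv maps an even H exactly to H/2.
"""

from __future__ import annotations

import numpy as np

from . import init as _init
from .module import Module
from .tensor import Parameter, Tensor, is_grad_enabled

__all__ = ["Conv2d", "BatchNorm2d", "Linear", "LayerNorm", "Dropout", "ReLU"]

_DTYPE = np.float32


def _conv2d(x: Tensor, w: Tensor, b: Tensor | None,
            stride: int, dilation: int) -> Tensor:
    """3x3/1x1 dilated, strided convolution via shifted-slice matmuls."""
    n, h, wd, cin = x.shape
    kh, kw, cin_w, cout = w.shape
    if cin != cin_w:
        raise ValueError(f"conv expects {cin_w} input channels, got {cin}")
    eff_h = (kh - 1) * dilation + 1
    eff_w = (kw - 1) * dilation + 1
    ho = -(-h // stride)
    wo = -(-wd // stride)
    pad_h = max((ho - 1) * stride + eff_h - h, 0)
    pad_w = max((wo - 1) * stride + eff_w - wd, 0)
    pt, pl = pad_h // 2, pad_w // 2
    xp = np.pad(x.data, ((0, 0), (pt, pad_h - pt), (pl, pad_w - pl), (0, 0)))

    acc = np.zeros((n * ho * wo, cout), dtype=x.data.dtype)
    hs = (ho - 1) * stride + 1
    ws = (wo - 1) * stride + 1
    for u in range(kh):
        for v in range(kw):
            sl = xp[:, u * dilation:u * dilation + hs:stride,
                    v * dilation:v * dilation + ws:stride, :]
            acc += sl.reshape(-1, cin) @ w.data[u, v]
    out_data = acc.reshape(n, ho, wo, cout)
    if b is not None:
        out_data = out_data + b.data

    req = (x.requires_grad or w.requires_grad
           or (b is not None and b.requires_grad)) and is_grad_enabled()
    if not req:
        return Tensor(out_data)

    def bw(g):
        gm = g.reshape(-1, cout)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        need_dx = x.requires_grad
        dxp = np.zeros_like(xp) if need_dx else None
        for u in range(kh):
            for v in range(kw):
                sl = xp[:, u * dilation:u * dilation + hs:stride,
                        v * dilation:v * dilation + ws:stride, :]
                if w.requires_grad:
                    w._accumulate_kernel(u, v, sl.reshape(-1, cin).T @ gm)
                if need_dx:
                    dxp[:, u * dilation:u * dilation + hs:stride,
                        v * dilation:v * dilation + ws:stride, :] += \
                        (gm @ w.data[u, v].T).reshape(n, ho, wo, cin)
        if need_dx:
            x._accumulate(dxp[:, pt:pt + h, pl:pl + wd, :])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, True, parents, bw)


class _KernelParameter(Parameter):
    """Conv weight with per-tap gradient accumulation."""

    __slots__ = ()

    def _accumulate_kernel(self, u: int, v: int, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad[u, v] += g


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        rng = rng if rng is not None else np.random.default_rng(0)
        k = kernel_size
        fan_in = k * k * in_channels
        w = _init.he_normal((k, k, in_channels, out_channels), fan_in, rng)
        self.weight = _KernelParameter(w.astype(_DTYPE))
        self.bias = Parameter(np.zeros(out_channels, dtype=_DTYPE)) if bias else None
        self.stride = stride
        self.dilation = dilation
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        return _conv2d(x, self.weight, self.bias, self.stride, self.dilation)


class BatchNorm2d(Module):
    """Batch normalisation over (batch, height, width) per channel.

    Running mean/variance are the network's only non-trainable parameters.
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=_DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=_DTYPE))
        self.running_mean = Parameter(np.zeros(channels, dtype=_DTYPE),
                                      trainable=False)
        self.running_var = Parameter(np.ones(channels, dtype=_DTYPE),
                                     trainable=False)
        self.momentum = momentum
        self.eps = eps
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.channels:
            raise ValueError(f"batchnorm expects {self.channels} channels, "
                             f"got {x.shape[-1]}")
        if self.training:
            mu = x.data.mean(axis=(0, 1, 2))
            var = x.data.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean.data = (m * self.running_mean.data
                                      + (1 - m) * mu).astype(_DTYPE)
            self.running_var.data = (m * self.running_var.data
                                     + (1 - m) * var).astype(_DTYPE)
        else:
            mu = self.running_mean.data
            var = self.running_var.data

        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out_data = (self.gamma.data * xhat + self.beta.data).astype(x.dtype,
                                                                    copy=False)
        req = (x.requires_grad or self.gamma.requires_grad) and is_grad_enabled()
        if not req:
            return Tensor(out_data)
        gamma, beta, training = self.gamma, self.beta, self.training

        def bw(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 1, 2)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 1, 2)))
            if x.requires_grad:
                if training:
                    nred = g.shape[0] * g.shape[1] * g.shape[2]
                    gx = g * gamma.data
                    t1 = gx.sum(axis=(0, 1, 2)) / nred
                    t2 = (gx * xhat).sum(axis=(0, 1, 2)) / nred
                    x._accumulate(inv * (gx - t1 - xhat * t2))
                else:
                    x._accumulate(g * gamma.data * inv)

        return Tensor(out_data, True, (x, gamma, beta), bw)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        w = _init.he_normal((in_dim, out_dim), in_dim, rng)
        self.weight = Parameter(w.astype(_DTYPE))
        self.bias = Parameter(np.zeros(out_dim, dtype=_DTYPE)) if bias else None
        self.in_dim = in_dim
        self.out_dim = out_dim

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"linear expects dim {self.in_dim}, got {x.shape[-1]}")
        from .tensor import matmul
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Normalisation over the last (embedding) axis of a token sequence."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=_DTYPE))
        self.beta = Parameter(np.zeros(dim, dtype=_DTYPE))
        self.eps = eps
        self.dim = dim

    def forward(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out_data = self.gamma.data * xhat + self.beta.data
        req = (x.requires_grad or self.gamma.requires_grad) and is_grad_enabled()
        if not req:
            return Tensor(out_data)
        gamma, beta, d = self.gamma, self.beta, self.dim

        def bw(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).reshape(-1, d).sum(axis=0))
            if beta.requires_grad:
                beta._accumulate(g.reshape(-1, d).sum(axis=0))
            if x.requires_grad:
                gx = g * gamma.data
                t1 = gx.mean(axis=-1, keepdims=True)
                t2 = (gx * xhat).mean(axis=-1, keepdims=True)
                x._accumulate(inv * (gx - t1 - xhat * t2))

        return Tensor(out_data, True, (x, gamma, beta), bw)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        from .tensor import relu
        return relu(x)
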
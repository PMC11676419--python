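"""Reverse-mode automatic differentiation on NumPy arrays.

A minimal tape-based engine: every operation returns a new :class:`Tensor`
holding its value, its parents and a closure that accumulates gradients into
them.  ``backward()`` runs the closures in reverse topological order.  Only
the operations needed by the segmentation network are implemented; all of
them work on float32 or float64 arrays and broadcast like NumPy.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "matmul",
    "softmax",
    "relu",
    "sigmoid",
    "log",
    "clip",
    "mean",
    "total",
    "upsample_nearest2x",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (), backward: Callable | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph -------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.dtype)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, True, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.dtype)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, True, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.dtype)
        out_data = self.data / other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return Tensor(out_data, True, (self, other), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other, self.dtype) / self

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        orig = self.shape

        def bw(g):
            self._accumulate(g.reshape(orig))

        return Tensor(out_data, True, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor(out_data, True, (self,), bw)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        shape, nd = self.shape, self.ndim

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).astype(self.dtype, copy=False))
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(a % nd for a in axes)
            if not keepdims:
                for a in sorted(axes):
                    g = np.expand_dims(g, a)
            self._accumulate(np.broadcast_to(g, shape).astype(self.dtype, copy=False))

        return Tensor(out_data, True, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype if dtype is not None else None)
    return Tensor(arr)


class Parameter(Tensor):
    """A leaf tensor registered by :class:`~strokeseg.nn.module.Module`.

    ``trainable=False`` marks bookkeeping state (batch-norm running
    statistics) that is stored and counted but never updated by gradients.
    """

    __slots__ = ("trainable",)

    def __init__(self, data, trainable: bool = True):
        super().__init__(np.asarray(data), requires_grad=trainable)
        self.trainable = trainable
        # parameters must survive no_grad blocks used during model building
        self.requires_grad = trainable


# --------------------------------------------------------------------------
# functional ops
# --------------------------------------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor(out_data, True, tuple(tensors), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with NumPy semantics (no batch broadcasting
    between operands of different batch shape, which the network never needs
    except matrix @ matrix and equal-batch cases)."""
    out_data = a.data @ b.data
    req = a.requires_grad or b.requires_grad
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return Tensor(out_data, True, (a, b), bw)


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0)
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)
    mask = x.data > 0

    def bw(g):
        x._accumulate(g * mask)

    return Tensor(out_data, True, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, True, (x,), bw)


def log(x: Tensor) -> Tensor:
    out_data = np.log(x.data)
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        x._accumulate(g / x.data)

    return Tensor(out_data, True, (x,), bw)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient is zero where the input was clamped."""
    out_data = np.clip(x.data, lo, hi)
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)
    mask = (x.data > lo) & (x.data < hi)

    def bw(g):
        x._accumulate(g * mask)

    return Tensor(out_data, True, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        inner = (g * out_data).sum(axis=axis, keepdims=True)
        x._accumulate(out_data * (g - inner))

    return Tensor(out_data, True, (x,), bw)


def mean(x: Tensor) -> Tensor:
    return x.mean()


def total(x: Tensor) -> Tensor:
    return x.sum()


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of an NHWC tensor."""
    out_data = x.data.repeat(2, axis=1).repeat(2, axis=2)
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)
    n, h, w, c = x.shape

    def bw(g):
        x._accumulate(g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)))

    return Tensor(out_data, True, (x,), bw)
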
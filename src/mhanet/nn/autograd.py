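"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and, while gradients are enabled,
records its provenance on a tape. :meth:`Tensor.backward` walks the tape in
reverse topological order. The op set is exactly what an encoder/decoder
segmentation network needs: convolution (plain, grouped, transposed), batch
norm, max-pool, ReLU/sigmoid/softmax, linear, concat/slice, broadcasting
add/mul, reductions, and a fused binary cross-entropy on logits.

Gradients of every op are hand-derived and checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

from . import functional as F

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode; intermediates are freed)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    """An ndarray with an optional gradient and tape record."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- autodiff ----------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free tape state so activation memory is reclaimed eagerly
                if node is not self:
                    node._backward = None

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise and structural ops ---------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def getitem(a: Tensor, key) -> Tensor:
    out_data = a.data[key]

    def backward(g):
        ga = np.zeros_like(a.data)
        ga[key] = g
        a._accumulate(ga)

    return _make(out_data, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def backward(g):
        offset = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + s)
                t._accumulate(g[tuple(sl)])
            offset += s

    return _make(out_data, tensors, backward)


def mean(a: Tensor, axis, keepdims: bool = False) -> Tensor:
    axis = tuple(axis) if isinstance(axis, (tuple, list)) else (axis,)
    n = int(np.prod([a.shape[ax] for ax in axis]))
    out_data = a.data.mean(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accumulate(np.broadcast_to(gg, a.shape) / n)

    return _make(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0)

    def backward(g):
        a._accumulate(g * (out_data > 0))

    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = _sigmoid(a.data)

    def backward(g):
        a._accumulate(g * out_data * (1 - out_data))

    return _make(out_data, (a,), backward)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(a: Tensor, axis: int) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    out_data = ez / ez.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - dot))

    return _make(out_data, (a,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (B,Cin) @ w.T (Cin,Cout) + b."""
    out_data = x.data @ w.data.T
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ w.data)
        if w.requires_grad:
            w._accumulate(g.T @ x.data)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


# -- spatial ops -----------------------------------------------------------


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    pad: int = 0,
    groups: int = 1,
) -> Tensor:
    out_data = F.conv2d(x.data, w.data, None if b is None else b.data, stride, pad, groups)

    def backward(g):
        if x.requires_grad:
            x._accumulate(F.conv2d_input_grad(g, w.data, x.shape, stride, pad, groups))
        if w.requires_grad:
            w._accumulate(F.conv2d_weight_grad(g, x.data, w.shape, stride, pad, groups))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2, pad: int = 1
) -> Tensor:
    """Transposed convolution; ``w`` has shape (Cin, Cout, kh, kw)."""
    B, Cin, H, W = x.shape
    _, Cout, kh, kw = w.shape
    oh, ow = F.conv_transpose2d_shape(H, W, kh, stride, pad)
    out_shape = (B, Cout, oh, ow)
    # forward of a transposed conv == input-gradient of the mirror conv
    out_data = F.conv2d_input_grad(x.data, w.data, out_shape, stride, pad)
    if b is not None:
        out_data += b.data.reshape(1, Cout, 1, 1)

    def backward(g):
        if x.requires_grad:
            x._accumulate(F.conv2d(g, w.data, None, stride, pad))
        if w.requires_grad:
            w._accumulate(F.conv2d_weight_grad(x.data, g, w.shape, stride, pad))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def maxpool2d(x: Tensor, k: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    out_data, idx = F.maxpool2d(x.data, k, stride, pad)

    def backward(g):
        x._accumulate(F.maxpool2d_grad(g, idx, x.shape, k, stride, pad))

    return _make(out_data, (x,), backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (B,H,W) per channel; mutates running stats
    in training mode."""
    c = x.shape[1]
    gshape = (1, c, 1, 1)
    if training:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
        running_mean += momentum * (m - running_mean)
        running_var += momentum * (v - running_var)
    else:
        m, v = running_mean, running_var
    inv_std = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m.reshape(gshape)) * inv_std.reshape(gshape)
    out_data = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = g * gamma.data.reshape(gshape)
            if training:
                n = x.data.size // c
                a = gs.sum(axis=(0, 2, 3), keepdims=True) / n
                bq = (gs * xhat).sum(axis=(0, 2, 3), keepdims=True) / n
                gx = inv_std.reshape(gshape) * (gs - a - xhat * bq)
            else:
                gx = gs * inv_std.reshape(gshape)
            x._accumulate(gx)

    return _make(out_data, (x, gamma, beta), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy evaluated stably on logits."""
    z = logits.data
    t = np.asarray(targets, dtype=z.dtype)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out_data = np.asarray(loss.mean(), dtype=z.dtype)

    def backward(g):
        logits._accumulate(g * (_sigmoid(z) - t) / z.size)

    return _make(out_data, (logits,), backward)
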
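"""Reverse-mode automatic differentiation over numpy arrays.

This is the numerical engine the network code in :mod:`chiraldiff.gcpnet`,
:mod:`chiraldiff.autoencoder` and :mod:`chiraldiff.diffusion` is built on.
It implements a small tape: every operation on :class:`Tensor` records a
closure that propagates gradients back to its operands, and
:meth:`Tensor.backward` walks the tape in reverse topological order.

All arrays are float64 throughout; the molecules handled here are tiny
(<= a dozen atoms), so accuracy is preferred over throughput.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy.special import expit

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape recording inside the block (used during sampling)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- tape ----------------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g


def _make(data, parents, backward) -> Tensor:
    """Build a result node; record on the tape only if gradients are live."""
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if not req:
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=tuple(parents), backward=backward)


# -- arithmetic ---------------------------------------------------------------


def add(a, b):
    a, b = Tensor.as_tensor(a), Tensor.as_tensor(b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bw)


def mul(a, b):
    a, b = Tensor.as_tensor(a), Tensor.as_tensor(b)
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bw)


def sub(a, b):
    return add(a, neg(b))


def neg(a):
    a = Tensor.as_tensor(a)

    def bw(g):
        a._accumulate(-g)

    return _make(-a.data, (a,), bw)


def div(a, b):
    a, b = Tensor.as_tensor(a), Tensor.as_tensor(b)
    out_data = a.data / b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(out_data, (a, b), bw)


def pow_(a, exponent: float):
    a = Tensor.as_tensor(a)
    out_data = a.data ** exponent

    def bw(g):
        a._accumulate(g * exponent * a.data ** (exponent - 1))

    return _make(out_data, (a,), bw)


def matmul(a, b):
    a, b = Tensor.as_tensor(a), Tensor.as_tensor(b)
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g @ b.data.swapaxes(-1, -2), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(a.data.swapaxes(-1, -2) @ g, b.data.shape))

    return _make(out_data, (a, b), bw)


# -- reductions / shape -------------------------------------------------------


def sum_(a, axis=None, keepdims=False):
    a = Tensor.as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), bw)


def mean(a, axis=None, keepdims=False):
    a = Tensor.as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape):
    a = Tensor.as_tensor(a)
    orig = a.data.shape

    def bw(g):
        a._accumulate(g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), bw)


def swapaxes(a, ax1, ax2):
    a = Tensor.as_tensor(a)

    def bw(g):
        a._accumulate(g.swapaxes(ax1, ax2))

    return _make(a.data.swapaxes(ax1, ax2), (a,), bw)


def _is_advanced(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return any(isinstance(k, (np.ndarray, list)) for k in items)


def getitem(a, idx):
    a = Tensor.as_tensor(a)
    advanced = _is_advanced(idx)

    def bw(g):
        full = np.zeros_like(a.data)
        if advanced:
            np.add.at(full, idx, g)
        else:
            full[idx] += g  # basic indexing (incl. None) yields a view
        a._accumulate(full)

    return _make(a.data[idx], (a,), bw)


def concatenate(tensors, axis=-1):
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(tensors), bw)


def stack(tensors, axis=0):
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return _make(out_data, tuple(tensors), bw)


def where(cond, a, b):
    """Select with a *constant* boolean condition (no gradient through cond)."""
    cond = np.asarray(cond)
    a, b = Tensor.as_tensor(a), Tensor.as_tensor(b)
    out_data = np.where(cond, a.data, b.data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(np.where(cond, g, 0.0), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.where(cond, 0.0, g), b.data.shape))

    return _make(out_data, (a, b), bw)


# -- elementwise nonlinearities ----------------------------------------------


def tanh(a):
    a = Tensor.as_tensor(a)
    t = np.tanh(a.data)

    def bw(g):
        a._accumulate(g * (1.0 - t ** 2))

    return _make(t, (a,), bw)


def sigmoid(a):
    a = Tensor.as_tensor(a)
    s = expit(a.data)

    def bw(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), bw)


def silu(a):
    a = Tensor.as_tensor(a)
    s = expit(a.data)
    out_data = a.data * s

    def bw(g):
        a._accumulate(g * (s + a.data * s * (1.0 - s)))

    return _make(out_data, (a,), bw)


def exp(a):
    a = Tensor.as_tensor(a)
    e = np.exp(a.data)

    def bw(g):
        a._accumulate(g * e)

    return _make(e, (a,), bw)


def log(a):
    a = Tensor.as_tensor(a)

    def bw(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), bw)


def sqrt(a):
    a = Tensor.as_tensor(a)
    r = np.sqrt(a.data)

    def bw(g):
        a._accumulate(g * 0.5 / r)

    return _make(r, (a,), bw)


# -- operator overloads -------------------------------------------------------

Tensor.__add__ = lambda self, other: add(self, other)
Tensor.__radd__ = lambda self, other: add(other, self)
Tensor.__sub__ = lambda self, other: sub(self, other)
Tensor.__rsub__ = lambda self, other: sub(other, self)
Tensor.__mul__ = lambda self, other: mul(self, other)
Tensor.__rmul__ = lambda self, other: mul(other, self)
Tensor.__truediv__ = lambda self, other: div(self, other)
Tensor.__rtruediv__ = lambda self, other: div(other, self)
Tensor.__neg__ = lambda self: neg(self)
Tensor.__pow__ = lambda self, exponent: pow_(self, exponent)
Tensor.__matmul__ = lambda self, other: matmul(self, other)
Tensor.__getitem__ = lambda self, idx: getitem(self, idx)
Tensor.sum = lambda self, axis=None, keepdims=False: sum_(self, axis, keepdims)
Tensor.mean = lambda self, axis=None, keepdims=False: mean(self, axis, keepdims)
Tensor.reshape = lambda self, *shape: reshape(
    self, shape[0] if len(shape) == 1 and isinstance(shape[0], (tuple, list)) else shape
)


# -- geometry helpers (differentiable) ----------------------------------------


def cross(a, b):
    """Cross product along the last axis (length 3)."""
    ax, ay, az = a[..., 0], a[..., 1], a[..., 2]
    bx, by, bz = b[..., 0], b[..., 1], b[..., 2]
    return stack([ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx], axis=-1)


def norm(a, axis=-1, keepdims=False, eps=0.0):
    """Euclidean norm; `eps` regularizes the square root at zero."""
    return sqrt(sum_(a * a, axis=axis, keepdims=keepdims) + eps)
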
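"""A small reverse-mode automatic differentiation engine on NumPy arrays.

Supports exactly the operations the graph network needs: broadcast
arithmetic, matrix products, row gather / segment scatter-sum (the sparse
message-passing primitives), concatenation, reductions and smooth
nonlinearities.  Gradients flow only into tensors created with
``requires_grad=True`` (parameters); feature matrices enter as constants.

Gradients are accumulated lazily (``None`` until first contribution); a
backward rule may hand over an alias of the incoming gradient, so no rule
ever mutates an accumulated ``grad`` array in place.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

# Training allocates many ~1 MB temporaries per step; above glibc's default
# mmap threshold each one becomes an mmap/munmap pair, which dominates the
# step time.  Raise the threshold so temporaries stay on the heap.
try:  # pragma: no cover - platform dependent
    import ctypes
    import ctypes.util

    _libc = ctypes.CDLL(ctypes.util.find_library("c"))
    _libc.mallopt(-3, 256 * 1024 * 1024)  # M_MMAP_THRESHOLD
except Exception:
    pass

_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "parents", "bwd", "requires_grad")

    def __init__(self, value, parents=(), bwd=None, requires_grad=False):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self.parents = parents
        self.bwd = bwd
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    def accum(self, g):
        self.grad = g if self.grad is None else self.grad + g

    # -- graph traversal ---------------------------------------------------
    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            t, done = stack.pop()
            if done:
                topo.append(t)
                continue
            if id(t) in seen or not t.requires_grad:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t.parents:
                stack.append((p, False))
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.value)
        for t in reversed(topo):
            if t.bwd is not None and t.grad is not None:
                t.bwd(t.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value + other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self.accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other.accum(_unbroadcast(g, other.shape))

        out.bwd = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))

        def bwd(g):
            if self.requires_grad:
                self.accum(-g)

        out.bwd = bwd
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value * other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self.accum(_unbroadcast(g * other.value, self.shape))
            if other.requires_grad:
                other.accum(_unbroadcast(g * self.value, other.shape))

        out.bwd = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value / other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self.accum(_unbroadcast(g / other.value, self.shape))
            if other.requires_grad:
                other.accum(_unbroadcast(-g * self.value / other.value ** 2, other.shape))

        out.bwd = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value @ other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self.accum(g @ other.value.T)
            if other.requires_grad:
                other.accum(self.value.T @ g)

        out.bwd = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(value) -> Tensor:
    return Tensor(np.array(value, dtype=float), requires_grad=True)


# -- elementwise nonlinearities ---------------------------------------------

def exp(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out = Tensor(np.exp(t.value), (t,))

    def bwd(g):
        if t.requires_grad:
            t.accum(g * out.value)

    out.bwd = bwd
    return out


def log(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out = Tensor(np.log(t.value), (t,))

    def bwd(g):
        if t.requires_grad:
            t.accum(g / t.value)

    out.bwd = bwd
    return out


def sigmoid(t: Tensor) -> Tensor:
    t = as_tensor(t)
    s = 1.0 / (1.0 + np.exp(-t.value))
    out = Tensor(s, (t,))

    def bwd(g):
        if t.requires_grad:
            t.accum(g * (s * (1.0 - s)))

    out.bwd = bwd
    return out


def tanh(t: Tensor) -> Tensor:
    t = as_tensor(t)
    v = np.tanh(t.value)
    out = Tensor(v, (t,))

    def bwd(g):
        if t.requires_grad:
            t.accum(g * (1.0 - v ** 2))

    out.bwd = bwd
    return out


def gelu(t: Tensor) -> Tensor:
    """Exact Gaussian-error-linear unit: x * Phi(x)."""
    t = as_tensor(t)
    x = t.value
    phi = 0.5 * (1.0 + erf(x / _SQRT2))
    out = Tensor(x * phi, (t,))

    def bwd(g):
        if t.requires_grad:
            t.accum(g * (phi + x * _INV_SQRT2PI * np.exp(-0.5 * x ** 2)))

    out.bwd = bwd
    return out


# -- shape / indexing --------------------------------------------------------

def gather(t: Tensor, idx) -> Tensor:
    """Select rows (axis 0); backward scatter-adds."""
    t = as_tensor(t)
    idx = np.asarray(idx, dtype=int)
    out = Tensor(t.value[idx], (t,))

    def bwd(g):
        if t.requires_grad:
            acc = np.zeros_like(t.value)
            np.add.at(acc, idx, g)
            t.accum(acc)

    out.bwd = bwd
    return out


def segment_sum(t: Tensor, idx, n: int) -> Tensor:
    """Sum rows of ``t`` into ``n`` buckets given by ``idx`` (axis 0)."""
    t = as_tensor(t)
    idx = np.asarray(idx, dtype=int)
    acc = np.zeros((n,) + t.value.shape[1:])
    np.add.at(acc, idx, t.value)
    out = Tensor(acc, (t,))

    def bwd(g):
        if t.requires_grad:
            t.accum(g[idx])

    out.bwd = bwd
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t.accum(piece)

    out.bwd = bwd
    return out


def reshape(t: Tensor, shape) -> Tensor:
    t = as_tensor(t)
    out = Tensor(t.value.reshape(shape), (t,))

    def bwd(g):
        if t.requires_grad:
            t.accum(g.reshape(t.value.shape))

    out.bwd = bwd
    return out


def tsum(t: Tensor, axis=None, keepdims=False) -> Tensor:
    t = as_tensor(t)
    out = Tensor(t.value.sum(axis=axis, keepdims=keepdims), (t,))

    def bwd(g):
        if t.requires_grad:
            if axis is None:
                t.accum(np.broadcast_to(g, t.value.shape))
            else:
                t.accum(np.broadcast_to(
                    np.expand_dims(g, axis) if not keepdims else g, t.value.shape
                ))

    out.bwd = bwd
    return out


def tmean(t: Tensor, axis=None, keepdims=False) -> Tensor:
    t = as_tensor(t)
    n = t.value.size if axis is None else t.value.shape[axis]
    return tsum(t, axis=axis, keepdims=keepdims) * (1.0 / n)


def softmax_1d(logits: Tensor) -> Tensor:
    """Softmax over a 1-D tensor (or (n,1) column)."""
    shift = float(logits.value.max())
    z = exp(logits - shift)
    return z / tsum(z)


def segment_softmax(logits: Tensor, idx, n: int) -> Tensor:
    """Softmax of 1-D ``logits`` normalised within segments given by ``idx``."""
    idx = np.asarray(idx, dtype=int)
    shift = np.full(n, -np.inf)
    np.maximum.at(shift, idx, logits.value)
    z = exp(logits - shift[idx])
    denom = segment_sum(z, idx, n)
    return z / gather(denom, idx)


ACTIVATIONS = {"gelu": gelu, "tanh": tanh, "sigmoid": sigmoid}
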
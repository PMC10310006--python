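"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps a float32 ``ndarray`` together with an optional
gradient buffer and the closure needed to propagate gradients to its
parents.  The op set is deliberately small — exactly what a convolutional
encoder, stacked LSTMs, multi-head attention and a Cox partial-likelihood
loss need — and every op is vectorised so the hot path stays inside BLAS.

Broadcasting follows NumPy semantics; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack"]

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=_DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "frozen", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward
        self.frozen = False       # used by optimizers for layer freezing
        self.name = None

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    # -------------------------------------------------------------- autograd
    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(_DTYPE, copy=True) if grad.dtype != _DTYPE else grad.copy()
        else:
            self.grad += grad

    def backward(self, grad=None):
        """Backpropagate from this tensor (default seed: ones)."""
        topo, seen = [], set()
        # iterative DFS to avoid recursion limits on long LSTM chains
        stack_ = [(self, False)]
        while stack_:
            t, processed = stack_.pop()
            if id(t) in seen or not t.requires_grad:
                continue
            if processed:
                seen.add(id(t))
                topo.append(t)
            else:
                stack_.append((t, True))
                for p in t._parents:
                    if id(p) not in seen and p.requires_grad:
                        stack_.append((p, False))

        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=_DTYPE))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, _parents=tuple(p for p in parents if p.requires_grad) if req else (),
                      _backward=backward if req else None)

    # ------------------------------------------------------------ arithmetic
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)
        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / (other.data ** 2), other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.expand_dims(g, -1) * other.data
                else:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.outer(self.data, g)
                else:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    # ------------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        # piecewise-stable form: never exponentiates a positive argument
        x = self.data
        pos = x >= 0
        ex = np.exp(np.where(pos, -x, x))
        out_data = np.where(pos, 1.0 / (1.0 + ex), ex / (1.0 + ex)).astype(_DTYPE)

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), bw)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).astype(_DTYPE))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).astype(_DTYPE))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def cumsum(self, axis=-1):
        out_data = np.cumsum(self.data, axis=axis)

        def bw(g):
            self._accumulate(np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis))

        return Tensor._make(out_data, (self,), bw)

    # ---------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(out_data, (self,), bw)

    def swapaxes(self, a, b):
        out_data = np.swapaxes(self.data, a, b)

        def bw(g):
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        basic = isinstance(idx, (slice, int)) or (
            isinstance(idx, tuple) and all(isinstance(i, (slice, int)) for i in idx))

        def bw(g):
            full = np.zeros_like(self.data)
            if basic:          # basic indexing never repeats elements
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(out_data, (self,), bw)

    # ----------------------------------------------------------- compositions
    def softmax(self, axis=-1):
        """Numerically stable softmax (max is treated as a constant shift)."""
        m = self.data.max(axis=axis, keepdims=True)
        e = (self - Tensor(m)).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis=None, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = (self - Tensor(m)).exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims and axis is not None:
            # squeeze the reduced axis
            sq = shifted.reshape(tuple(s for i, s in enumerate(shifted.shape)
                                       if i != (axis % self.data.ndim)))
            return sq
        if not keepdims and axis is None:
            return shifted.reshape(())
        return shifted

    def logcumsumexp(self, axis=-1):
        """log of the running sum of exp along ``axis`` (global max-shift)."""
        m = float(self.data.max()) if self.data.size else 0.0
        return (self - m).exp().cumsum(axis=axis).log() + m


def concatenate(tensors, axis=0):
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


def stack(tensors, axis=0):
    expanded = []
    for t in tensors:
        t = Tensor._coerce(t)
        shp = list(t.shape)
        shp.insert(axis if axis >= 0 else len(shp) + 1 + axis, 1)
        expanded.append(t.reshape(tuple(shp)))
    return concatenate(expanded, axis=axis)
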
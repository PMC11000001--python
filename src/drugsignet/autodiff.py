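"""Minimal reverse-mode automatic differentiation over numpy arrays.

The recurrent signaling model needs gradients through ~120 update steps,
batch normalization, a power iteration for the spectral radius, and
integrated-gradient attributions.  This module provides a small tape-based
engine (a :class:`Tensor` wrapping a float64 ``numpy`` array) with exactly
the primitives those computations use.  Operations on tensors where no
input requires a gradient short-circuit to constants, so inference-mode
forward passes carry no tape overhead.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ core
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every reachable leaf."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if seed is None:
            seed = np.ones_like(self.data)
        self.grad = np.asarray(seed, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ----------------------------------------------------------- constructors
    @staticmethod
    def _op(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, parents=parents, backward=backward)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g, dtype=np.float64)
        else:
            self.grad += g

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._op(out_data, (self, other), None)._with_bwd(bwd, (self, other))

    def _with_bwd(self, bwd, parents):
        # _op already decided requires_grad; attach the closure only if needed
        if self.requires_grad:
            self._backward = bwd
        return self

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._op(-self.data, (self,), None)._with_bwd(bwd, (self,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._op(self.data * other.data, (self, other), None)._with_bwd(bwd, (self, other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._op(self.data / other.data, (self, other), None)._with_bwd(bwd, (self, other))

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))

        return Tensor._op(self.data ** e, (self,), None)._with_bwd(bwd, (self,))

    def __matmul__(self, other):
        other = _as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._op(self.data @ other.data, (self, other), None)._with_bwd(bwd, (self, other))

    # ---------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * od)

        return Tensor._op(out_data, (self,), None)._with_bwd(bwd, (self,))

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * 0.5 / od)

        return Tensor._op(out_data, (self,), None)._with_bwd(bwd, (self,))

    def abs(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g * np.sign(a.data))

        return Tensor._op(np.abs(self.data), (self,), None)._with_bwd(bwd, (self,))

    def relu(self):
        mask = self.data > 0

        def bwd(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor._op(self.data * mask, (self,), None)._with_bwd(bwd, (self,))

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        def bwd(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)._with_bwd(bwd, (self,))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Max along an axis; gradient flows to the first arg-max entry."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis)

        def bwd(g, a=self, ix=idx, ax=axis):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.put_along_axis(full, np.expand_dims(ix, ax), np.expand_dims(g, ax), axis=ax)
                a._accum(full)

        return Tensor._op(out_data, (self,), None)._with_bwd(bwd, (self,))

    def min(self, axis: int):
        return -((-self).max(axis=axis))

    # ----------------------------------------------------------- structural
    @property
    def T(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g.T)

        return Tensor._op(self.data.T, (self,), None)._with_bwd(bwd, (self,))

    def take_cols(self, idx: np.ndarray):
        """Select columns (last axis) by integer index."""
        idx = np.asarray(idx)

        def bwd(g, a=self, ix=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, (slice(None), ix), g)
                a._accum(full)

        return Tensor._op(self.data[:, idx], (self,), None)._with_bwd(bwd, (self,))

    def scatter_to(self, rows: np.ndarray, cols: np.ndarray, shape: tuple):
        """Place a 1-D value vector at (rows, cols) of a dense zero matrix."""
        out_data = np.zeros(shape)
        out_data[rows, cols] = self.data

        def bwd(g, a=self, r=rows, c=cols):
            if a.requires_grad:
                a._accum(g[r, c])

        return Tensor._op(out_data, (self,), None)._with_bwd(bwd, (self,))

    def mask(self, m: np.ndarray):
        """Multiply by a constant 0/1 (or any constant) array."""
        def bwd(g, a=self, mm=m):
            if a.requires_grad:
                a._accum(_unbroadcast(g * mm, a.data.shape))

        return Tensor._op(self.data * m, (self,), None)._with_bwd(bwd, (self,))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)
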
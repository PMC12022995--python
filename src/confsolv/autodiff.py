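"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine exists because the solvent-model energies must be differentiated
twice: forces are ``-dE/dx``, and force-matching training then needs the
gradient of a force-based loss with respect to the network weights.  To make
that possible every backward rule is expressed in terms of :class:`Tensor`
operations, so the graph produced by one call to :func:`grad` can itself be
differentiated again.

Only the small set of primitives the package needs is implemented: arithmetic
with broadcasting, ``exp``/``log``/``tanh``/``sqrt``/``pow``, reductions,
2-D matmul, row gather/scatter, column concatenation and a data-dependent
``where``.  Shapes are plain NumPy shapes; no device or dtype machinery.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "grad", "concat_cols", "where",
           "take_rows", "scatter_add_rows", "softplus", "sigmoid", "silu"]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "parents")

    def __init__(self, data, parents: Sequence[tuple["Tensor", Callable]] = ()):
        self.data = np.asarray(data, dtype=float)
        self.parents = tuple(parents)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(self.data + other.data, [
            (self, lambda g: _unbroadcast(g, self.shape)),
            (other, lambda g: _unbroadcast(g, other.shape)),
        ])

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor(self.data - other.data, [
            (self, lambda g: _unbroadcast(g, self.shape)),
            (other, lambda g: _unbroadcast(-g, other.shape)),
        ])

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(self.data * other.data, [
            (self, lambda g: _unbroadcast(g * other, self.shape)),
            (other, lambda g: _unbroadcast(g * self, other.shape)),
        ])

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(self.data / other.data, [
            (self, lambda g: _unbroadcast(g / other, self.shape)),
            (other, lambda g: _unbroadcast(-g * self / (other * other), other.shape)),
        ])

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return Tensor(-self.data, [(self, lambda g: -g)])

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        e = float(exponent)
        return Tensor(self.data ** e, [
            (self, lambda g: g * (self ** (e - 1.0)) * e),
        ])

    # -- elementwise functions ----------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data))
        out.parents = ((self, lambda g: g * out),)
        return out

    def log(self):
        return Tensor(np.log(self.data), [(self, lambda g: g / self)])

    def sqrt(self):
        out = Tensor(np.sqrt(self.data))
        out.parents = ((self, lambda g: g / (out * 2.0)),)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data))
        out.parents = ((self, lambda g: g * (1.0 - out * out)),)
        return out

    # -- shape ops ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def back(g):
            if axis is None:
                return g.broadcast_to(shape)
            gk = g if keepdims else g.reshape(_keepdims_shape(shape, axis))
            return gk.broadcast_to(shape)

        return Tensor(data, [(self, back)])

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, shape):
        old = self.shape
        return Tensor(self.data.reshape(shape), [(self, lambda g: g.reshape(old))])

    def broadcast_to(self, shape):
        return Tensor(np.broadcast_to(self.data, shape).copy(),
                      [(self, lambda g: _unbroadcast(g, self.shape))])

    @property
    def T(self):
        return Tensor(self.data.T.copy(), [(self, lambda g: g.T)])

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor(self.data @ other.data, [
            (self, lambda g: g @ other.T),
            (other, lambda g: self.T @ g),
        ])

    def slice_cols(self, start: int, stop: int):
        """Columns [start, stop) of a 2-D tensor."""
        n_cols = self.shape[1]
        shape = self.shape

        def back(g):
            left = Tensor(np.zeros((shape[0], start)))
            right = Tensor(np.zeros((shape[0], n_cols - stop)))
            return concat_cols([left, g, right])

        return Tensor(self.data[:, start:stop].copy(), [(self, back)])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _keepdims_shape(shape, axis):
    axes = (axis,) if np.isscalar(axis) else tuple(axis)
    return tuple(1 if i in axes or i - len(shape) in axes else s
                 for i, s in enumerate(shape))


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    if g.shape == tuple(shape):
        return g
    extra = len(g.shape) - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def concat_cols(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 1."""
    tensors = [as_tensor(t) for t in tensors]
    widths = [t.shape[1] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(widths)])
    parents = []
    for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
        parents.append((t, lambda g, a=int(a), b=int(b): g.slice_cols(a, b)))
    return Tensor(np.concatenate([t.data for t in tensors], axis=1), parents)


def where(cond: np.ndarray, a, b) -> Tensor:
    """Elementwise select with a *constant* boolean condition.

    The condition is data, not a graph node; gradients flow through the
    selected branch only.  Piecewise functions built this way are
    differentiable away from the switching surface.
    """
    a, b = as_tensor(a), as_tensor(b)
    cond = np.asarray(cond, dtype=bool)
    zero = Tensor(0.0)
    return Tensor(np.where(cond, a.data, b.data), [
        (a, lambda g: _unbroadcast(where(cond, g, zero.broadcast_to(g.shape)), a.shape)),
        (b, lambda g: _unbroadcast(where(cond, zero.broadcast_to(g.shape), g), b.shape)),
    ])


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows ``x[idx]``; the adjoint scatter-adds back."""
    idx = np.asarray(idx, dtype=int)
    n = x.shape[0]
    return Tensor(x.data[idx], [(x, lambda g: scatter_add_rows(g, idx, n))])


def scatter_add_rows(x: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """Accumulate rows of ``x`` into ``n`` output rows at positions ``idx``."""
    idx = np.asarray(idx, dtype=int)
    out = np.zeros((n,) + x.data.shape[1:])
    np.add.at(out, idx, x.data)
    return Tensor(out, [(x, lambda g: take_rows(g, idx))])


# -- composite activations --------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    # tanh form is bounded, so no overflow in either direction
    return (as_tensor(x) * 0.5).tanh() * 0.5 + 0.5


def softplus(x: Tensor) -> Tensor:
    x = as_tensor(x)
    big = x.data > 30.0
    safe = where(big, Tensor(np.zeros_like(x.data)), x)
    return where(big, x, (1.0 + safe.exp()).log())


def silu(x: Tensor) -> Tensor:
    return as_tensor(x) * sigmoid(x)


# -- backward ---------------------------------------------------------------

def _topo_order(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order


def grad(output: Tensor, wrt: Sequence[Tensor]) -> list[Tensor]:
    """Gradients of scalar ``output`` w.r.t. each tensor in ``wrt``.

    Returns differentiable :class:`Tensor` gradients (zeros for tensors the
    output does not depend on), enabling higher-order differentiation.
    """
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")
    grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    for node in reversed(_topo_order(output)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if id(node) in {id(w) for w in wrt}:
            # keep gradients of requested tensors
            grads[id(node)] = g
        for parent, vjp in node.parents:
            contrib = vjp(g)
            prev = grads.get(id(parent))
            grads[id(parent)] = contrib if prev is None else prev + contrib
    return [grads.get(id(w), Tensor(np.zeros_like(w.data))) for w in wrt]
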
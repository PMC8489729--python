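"""Reverse-mode automatic differentiation over numpy arrays.

This is the numerical engine under every network in the package: a small
define-by-run tape with exactly the primitives the encoder/decoder stacks and
the loss terms need (broadcast arithmetic, matmul, strided convolutions,
log-sum-exp, slicing/concatenation). Gradients are validated against central
finite differences in the test suite.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast up from `shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus a gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = requires_grad
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.requires_grad = any(p.requires_grad for p in parents)
        out.grad = None
        out._parents = tuple(p for p in parents if p.requires_grad) if out.requires_grad else ()
        out._backward = backward if out.requires_grad else None
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g

    def zero_grad(self):
        self.grad = None

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float, np.integer, np.floating)):
            a, s = self, float(other)

            def backward(g):
                return ((a, g),)

            return Tensor._result(a.data + s, (a,), backward)
        other = Tensor._wrap(other)
        a, b = self, other
        out_data = a.data + b.data

        def backward(g):
            return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

        return Tensor._result(out_data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float, np.integer, np.floating)):
            a, s = self, float(other)

            def backward(g):
                return ((a, g * s),)

            return Tensor._result(a.data * s, (a,), backward)
        other = Tensor._wrap(other)
        a, b = self, other
        out_data = a.data * b.data

        def backward(g):
            return ((a, _unbroadcast(g * b.data, a.data.shape)),
                    (b, _unbroadcast(g * a.data, b.data.shape)))

        return Tensor._result(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        a = self

        def backward(g):
            return ((a, -g),)

        return Tensor._result(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float, np.integer, np.floating)):
            return self * (1.0 / float(other))
        other = Tensor._wrap(other)
        a, b = self, other
        out_data = a.data / b.data

        def backward(g):
            return ((a, _unbroadcast(g / b.data, a.data.shape)),
                    (b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)))

        return Tensor._result(out_data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def backward(g):
            return ((a, g * p * a.data ** (p - 1)),)

        return Tensor._result(out_data, (a,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            if a.data.ndim == 1 and b.data.ndim == 1:
                return ((a, g * b.data), (b, g * a.data))
            if a.data.ndim == 1:
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.outer(a.data, g) if b.data.ndim == 2 else None
                return ((a, _unbroadcast(ga, a.data.shape)), (b, gb))
            if b.data.ndim == 1:
                ga = np.expand_dims(g, -1) * b.data
                gb = np.swapaxes(a.data, -1, -2) @ g
                return ((a, _unbroadcast(ga, a.data.shape)),
                        (b, _unbroadcast(gb, b.data.shape)))
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return ((a, _unbroadcast(ga, a.data.shape)),
                    (b, _unbroadcast(gb, b.data.shape)))

        return Tensor._result(out_data, (a, b), backward)

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            return ((a, g * out_data),)

        return Tensor._result(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            return ((a, g / a.data),)

        return Tensor._result(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            return ((a, g * 0.5 / out_data),)

        return Tensor._result(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            return ((a, g * mask),)

        return Tensor._result(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            return ((a, g * out_data * (1.0 - out_data)),)

        return Tensor._result(out_data, (a,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return ((a, np.broadcast_to(g, a.data.shape).copy()),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for d in sorted(ax):
                    g = np.expand_dims(g, d % a.data.ndim)
            return ((a, np.broadcast_to(g, a.data.shape).copy()),)

        return Tensor._result(out_data, (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[d] for d in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def backward(g):
            return ((a, g.reshape(old)),)

        return Tensor._result(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        a = self
        inv = np.argsort(axes)

        def backward(g):
            return ((a, g.transpose(inv)),)

        return Tensor._result(a.data.transpose(axes), (a,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            return ((a, full),)

        return Tensor._result(a.data[idx], (a,), backward)


def concat(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out.append((t, g[tuple(sl)]))
        return tuple(out)

    return Tensor._result(data, tuple(tensors), backward)


def logsumexp(t: Tensor, axis=None, keepdims=False):
    """Numerically stable log-sum-exp with exact softmax gradient."""
    a = t
    m = np.max(a.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    shifted = np.exp(a.data - m)
    s = shifted.sum(axis=axis, keepdims=True)
    out_full = np.log(s) + m
    if keepdims:
        out_data = out_full
    elif axis is None:
        out_data = out_full.reshape(())
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        out_data = np.squeeze(out_full, axis=ax)

    softmax = shifted / s

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            for d in sorted(a_d % a.data.ndim for a_d in ax):
                g = np.expand_dims(g, d)
        return ((a, g * softmax),)

    return Tensor._result(out_data, (a,), backward)
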
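"""A small reverse-mode automatic-differentiation engine on numpy arrays.

The networks in this package are trained on CPU with float32 arrays.  The
engine is define-by-run: every operation on :class:`Tensor` records a closure
that accumulates gradients into its parents; :meth:`Tensor.backward` walks the
graph in reverse topological order.  Only the operations the segmentation
models need are provided — this is a deliberate, compact core, not a general
framework.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import special as _special

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """An n-d array with an optional gradient and autograd history."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        req = any(p.requires_grad for p in parents)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        else:
            out._parents = ()
            out._backward = None
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- backward pass --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._coerce(other)
        data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._result(data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._result(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._result(data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        data = self.data**p

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._result(data, (self,), bw)

    def __matmul__(self, other):
        """Matrix product; batched over leading dims when both are rank-3."""
        other = Tensor._coerce(other)
        data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accum(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape)
                )
            if other.requires_grad:
                other._accum(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape)
                )

        return Tensor._result(data, (self, other), bw)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * data)

        return Tensor._result(data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._result(np.log(self.data), (self,), bw)

    def sqrt(self):
        data = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / data)

        return Tensor._result(data, (self,), bw)

    def tanh(self):
        data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - data**2))

        return Tensor._result(data, (self,), bw)

    def erf(self):
        data = _special.erf(self.data).astype(DTYPE)
        x = self.data

        def bw(g):
            if self.requires_grad:
                self._accum(g * (2.0 / np.sqrt(np.pi)) * np.exp(-(x**2)))

        return Tensor._result(data, (self,), bw)

    def sigmoid(self):
        data = _special.expit(self.data).astype(DTYPE)

        def bw(g):
            if self.requires_grad:
                self._accum(g * data * (1.0 - data))

        return Tensor._result(data, (self,), bw)

    def maximum(self, other):
        other = Tensor._coerce(other)
        data = np.maximum(self.data, other.data)
        mask = (self.data >= other.data).astype(DTYPE)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * (1.0 - mask), other.data.shape))

        return Tensor._result(data, (self, other), bw)

    def minimum(self, other):
        other = Tensor._coerce(other)
        data = np.minimum(self.data, other.data)
        mask = (self.data <= other.data).astype(DTYPE)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * (1.0 - mask), other.data.shape))

        return Tensor._result(data, (self, other), bw)

    def abs(self):
        sign = np.sign(self.data).astype(DTYPE)

        def bw(g):
            if self.requires_grad:
                self._accum(g * sign)

        return Tensor._result(np.abs(self.data), (self,), bw)

    def clip(self, lo: float, hi: float):
        data = np.clip(self.data, lo, hi)
        mask = ((self.data >= lo) & (self.data <= hi)).astype(DTYPE)

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._result(data, (self,), bw)

    # -- reductions and reshapes ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(DTYPE))
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, self.data.shape).astype(DTYPE))

        return Tensor._result(np.asarray(data, dtype=DTYPE), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis, keepdims: bool = False):
        axes = axis if isinstance(axis, tuple) else (axis,)
        data = self.data.max(axis=axes, keepdims=True)
        mask = (self.data == data).astype(DTYPE)
        # ties share the gradient equally
        mask /= np.maximum(mask.sum(axis=axes, keepdims=True), 1.0)
        out_data = data if keepdims else data.squeeze(axes)

        def bw(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accum(mask * g)

        return Tensor._result(out_data, (self,), bw)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        data = self.data.reshape(shape)

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._result(data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        data = self.data.transpose(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._result(data, (self,), bw)

    def __getitem__(self, idx):
        data = self.data[idx]

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._result(data, (self,), bw)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._result(data, ts, bw)
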
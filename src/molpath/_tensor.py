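"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are small (molecular graphs of a few dozen
atoms, feature widths of at most a few hundred), so a lightweight tape
suffices: every op records its parents and a closure that accumulates
gradients into them.  All arithmetic is float64; gradients are exact up to
floating point, which the finite-difference tests rely on.

Only the ops the model needs are provided.  ``maximum`` routes the
subgradient to its first argument on exact ties.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "maximum", "softmax"]

ArrayLike = "np.ndarray | float | int | Sequence"


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other: "Tensor | ArrayLike") -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g: np.ndarray) -> None:
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        data = self.data / other.data

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data ** 2, other.data.shape))

        return self._make(data, (self, other), backward)

    def __matmul__(self, other):
        """Matrix product; ``other`` must be 2-D, self may carry batch dims."""
        other = self._lift(other)
        if other.data.ndim != 2:
            raise ValueError("matmul: right operand must be 2-D")
        data = self.data @ other.data

        def backward(g: np.ndarray) -> None:
            self._accumulate(g @ other.data.T)
            a2 = self.data.reshape(-1, self.data.shape[-1])
            g2 = g.reshape(-1, g.shape[-1])
            other._accumulate(a2.T @ g2)

        return self._make(data, (self, other), backward)

    def __pow__(self, exponent: float):
        data = self.data ** exponent

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._make(data, (self,), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * out * (1.0 - out))

        return self._make(out, (self,), backward)

    def log(self):
        def backward(g: np.ndarray) -> None:
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def exp(self):
        out = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * out)

        return self._make(out, (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def sum(self, axis: int | tuple[int, ...] | None = None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return self._make(data, (self,), backward)

    def reshape(self, *shape: int):
        orig = self.data.shape
        data = self.data.reshape(*shape)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g.reshape(orig))

        return self._make(data, (self,), backward)

    @property
    def T(self) -> "Tensor":
        if self.data.ndim != 2:
            raise ValueError("T is defined for 2-D tensors only")
        data = self.data.T

        def backward(g: np.ndarray) -> None:
            self._accumulate(g.T)

        return self._make(data, (self,), backward)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- autodiff machinery ---------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if not (self.requires_grad or self._parents):
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on non-scalar requires an explicit grad")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if not node.requires_grad:
                    node.grad = None  # free intermediates

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    ts = list(tensors)
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out = Tensor(data)
    if any(t.requires_grad or t._parents for t in ts):
        out._parents = tuple(ts)
        out._backward = backward
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise maximum; ties send the gradient to ``a``."""
    take_a = a.data >= b.data
    data = np.where(take_a, a.data, b.data)

    def backward(g: np.ndarray) -> None:
        a._accumulate(_unbroadcast(g * take_a, a.data.shape))
        b._accumulate(_unbroadcast(g * ~take_a, b.data.shape))

    out = Tensor(data)
    if any(t.requires_grad or t._parents for t in (a, b)):
        out._parents = (a, b)
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant: no gradient
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
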
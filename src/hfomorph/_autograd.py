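"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for dense residual networks: broadcasting arithmetic,
matrix products, elementwise nonlinearities, and reductions. Values are
float64 throughout; gradients accumulate into ``Tensor.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "relu", "sigmoid", "tanh", "exp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = lambda: None
        self._prev = _prev

    # -- construction helpers -------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def _backward():
            self._accum(_unbroadcast(out.grad, self.data.shape))
            other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def _backward():
            self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, self.requires_grad, (self,))

        def _backward():
            self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = _backward
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, self._needs(other), (self, other))

        def _backward():
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)

        out._backward = _backward
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def _backward():
            grad = out.grad
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accum(np.broadcast_to(grad, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()

        def build(node: "Tensor") -> None:
            if id(node) in visited:
                return
            visited.add(id(node))
            for prev in node._prev:
                build(prev)
            topo.append(node)

        build(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is not None:  # constant subgraphs receive no gradient
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))

    def _backward():
        x._accum(out.grad * (x.data > 0))

    out._backward = _backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, x.requires_grad, (x,))

    def _backward():
        x._accum(out.grad * s * (1.0 - s))

    out._backward = _backward
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, x.requires_grad, (x,))

    def _backward():
        x._accum(out.grad * (1.0 - t**2))

    out._backward = _backward
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = Tensor(e, x.requires_grad, (x,))

    def _backward():
        x._accum(out.grad * e)

    out._backward = _backward
    return out
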
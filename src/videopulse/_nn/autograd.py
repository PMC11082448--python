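"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine purpose-built for the pulse-extraction networks in
this package: dense/convolutional layers over frame batches, temporal
convolutions and causal FIR taps along the time axis, pooling, elementwise
nonlinearities and reductions.  Arrays are float64 throughout; gradients are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":  # floats keep their precision (f32 or f64)
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort; graphs can be deep in T
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic -------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (self._accumulate(g), other._accumulate(g)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: self._accumulate(-g))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                self._accumulate(g * other.data),
                other._accumulate(g * self.data),
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                self._accumulate(g / other.data),
                other._accumulate(-g * self.data / other.data**2),
            ),
        )
        return out

    def __pow__(self, exponent: float):
        out = Tensor._make(
            self.data**exponent,
            (self,),
            lambda g: self._accumulate(g * exponent * self.data ** (exponent - 1)),
        )
        return out

    # -- nonlinearities ----------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        return Tensor._make(y, (self,), lambda g, y=y: self._accumulate(g * (1 - y**2)))

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(y, (self,), lambda g, y=y: self._accumulate(g * y * (1 - y)))

    # -- reductions & shaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape),
            (self,),
            lambda g: self._accumulate(np.asarray(g).reshape(orig)),
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(
            np.ascontiguousarray(self.data.transpose(*axes)),
            (self,),
            lambda g: self._accumulate(np.asarray(g).transpose(*inv)),
        )

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)
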
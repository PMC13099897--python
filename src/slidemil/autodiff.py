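"""Minimal reverse-mode automatic differentiation on numpy arrays.

The MIL models in this package are small attention networks (a few dense
layers per slide bag), so a compact tape-based engine is sufficient: a
:class:`Tensor` wraps an ``ndarray``, records its parents and a backward
closure, and :meth:`Tensor.backward` walks the tape in reverse topological
order. Gradients are checked against central finite differences in the test
suite.

Only the primitives the models need are implemented: elementwise arithmetic,
matmul, transpose, row gathering, reductions, tanh / sigmoid / GELU / exp /
log / power, stabilized softmax, and value clipping (straight-through
gradient inside the clip range).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "param", "glorot"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, _parents=parents, _backward=backward)
        return out

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            return (g * e * np.power(self.data, e - 1.0),)

        return self._make(np.power(self.data, e), (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            ga = g @ other.data.T if other.data.ndim == 2 else np.outer(g, other.data)
            gb = self.data.T @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        return self._make(self.data.T, (self,), lambda g: (g.T,))

    def take_rows(self, idx) -> "Tensor":
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return self._make(self.data[idx], (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        orig = self.shape
        return self._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------------
    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        return self._make(y, (self,), lambda g: (g * (1.0 - y * y),))

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        return self._make(y, (self,), lambda g: (g * y * (1.0 - y),))

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        return self._make(y, (self,), lambda g: (g * y,))

    def log(self) -> "Tensor":
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def gelu(self) -> "Tensor":
        """Exact GELU, x * Phi(x), with Phi the standard normal CDF."""
        from scipy.special import ndtr

        phi_cdf = ndtr(self.data)
        pdf = np.exp(-0.5 * self.data ** 2) / math.sqrt(2.0 * math.pi)

        def backward(g):
            return (g * (phi_cdf + self.data * pdf),)

        return self._make(self.data * phi_cdf, (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes through only where unclipped."""
        inside = (self.data >= lo) & (self.data <= hi)
        return self._make(np.clip(self.data, lo, hi), (self,), lambda g: (g * inside,))

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        return self._make(y, (self,), backward)

    # -- backward pass --------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def param(data) -> Tensor:
    """Wrap an array as a trainable parameter."""
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    """Glorot-uniform initialized weight matrix of shape (fan_in, fan_out)."""
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return param(rng.uniform(-limit, limit, size=(fan_in, fan_out)))


class Adam:
    """Adam optimizer with optional decoupled-free L2 penalty added to the gradient."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: Sequence[float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = self.b1 * self._m[i] + (1.0 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1.0 - self.b2) * g * g
            mhat = self._m[i] / (1.0 - self.b1 ** self._t)
            vhat = self._v[i] / (1.0 - self.b2 ** self._t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
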
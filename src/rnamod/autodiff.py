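"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The toolkit trains deliberately small transformer encoders on CPU, so instead
of pulling in a deep-learning framework the model layer is written against
this compact tensor/autograd engine: a :class:`Tensor` wraps an ``ndarray``,
records its parents and a gradient function per parent, and ``backward()``
walks the graph in reverse topological order.

Conventions
-----------
* All arithmetic is float64.
* Gradients on leaves (``requires_grad=True``) accumulate across successive
  ``backward()`` calls until ``zero_grad`` — this is what lets the
  adversarial trainer combine the clean and perturbed passes into a single
  optimizer step.
* Non-leaf tensors discard their gradient unless ``retain_grad()`` was
  called; the FGM step retains the embedding-output gradient this way.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "no_grad", "sigmoid", "gelu", "relu", "softmax", "layer_norm"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False

_SQRT_2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient and a backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_retain")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # list of (parent_tensor, fn mapping out-grad -> parent-grad contribution)
        self._parents: list[tuple["Tensor", Callable[[np.ndarray], np.ndarray]]] = []
        self._retain = False

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data: np.ndarray, parents) -> "Tensor":
        out = Tensor(data)
        if not _grad_enabled:
            return out
        live = [(p, fn) for p, fn in parents if p.requires_grad or p._parents]
        out._parents = live
        out.requires_grad = bool(live)
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def retain_grad(self) -> "Tensor":
        self._retain = True
        return self

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        data = self.data + other.data
        return Tensor._make(
            data,
            [
                (self, lambda g, s=self.data.shape: _unbroadcast(g, s)),
                (other, lambda g, s=other.data.shape: _unbroadcast(g, s)),
            ],
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        data = self.data * other.data
        return Tensor._make(
            data,
            [
                (self, lambda g, o=other.data, s=self.data.shape: _unbroadcast(g * o, s)),
                (other, lambda g, o=self.data, s=other.data.shape: _unbroadcast(g * o, s)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)
        data = self.data ** e
        return Tensor._make(
            data,
            [(self, lambda g, x=self.data: g * e * x ** (e - 1.0))],
        )

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        data = self.data @ other.data

        def grad_a(g, a=self.data, b=other.data):
            gb = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.multiply.outer(g, b)
            return _unbroadcast(gb, a.shape)

        def grad_b(g, a=self.data, b=other.data):
            ga = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.multiply.outer(a, g)
            return _unbroadcast(ga, b.shape)

        return Tensor._make(data, [(self, grad_a), (other, grad_b)])

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self) -> "Tensor":
        data = np.exp(self.data)
        return Tensor._make(data, [(self, lambda g, d=data: g * d)])

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), [(self, lambda g, x=self.data: g / x)])

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)
        return Tensor._make(data, [(self, lambda g, d=data: g * (1.0 - d * d))])

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g, shape=self.data.shape):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return np.broadcast_to(gg, shape).copy()

        return Tensor._make(data, [(self, grad_fn)])

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)
        return Tensor._make(
            data, [(self, lambda g, s=self.data.shape: g.reshape(s))]
        )

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        return Tensor._make(
            self.data.transpose(axes), [(self, lambda g: g.transpose(inv))]
        )

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]

        def grad_fn(g, shape=self.data.shape):
            out = np.zeros(shape)
            np.add.at(out, idx, g)
            return out

        return Tensor._make(np.array(data, copy=True), [(self, grad_fn)])

    # -- backward -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        # reverse topological order (iterative DFS)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in visited:
                    stack.append((parent, False))

        pending: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = pending.pop(id(node), None)
            if g is None:
                continue
            if (node.requires_grad and not node._parents) or node._retain:
                node.grad = g.copy() if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                contrib = fn(g)
                key = id(parent)
                if key in pending:
                    pending[key] = pending[key] + contrib
                else:
                    pending[key] = contrib


# -- functional layer ---------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._make(data, [(x, lambda g, d=data: g * d * (1.0 - d))])


def relu(x: Tensor) -> Tensor:
    data = np.maximum(x.data, 0.0)
    return Tensor._make(data, [(x, lambda g, m=(x.data > 0): g * m)])


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    v = x.data
    phi = 0.5 * (1.0 + erf(v / _SQRT_2))
    data = v * phi

    def grad_fn(g, v=v, phi=phi):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * v * v)
        return g * (phi + v * pdf)

    return Tensor._make(data, [(x, grad_fn)])


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x.data.max(axis=axis, keepdims=True)  # constant: does not need grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then affine."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * gain + bias
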
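"""A small reverse-mode automatic-differentiation tape over numpy arrays.

Supports exactly the operations the discrete-time cell needs — elementwise
arithmetic with broadcasting, matrix products, sqrt, square, rectification
(with subgradient 0 at the corner), logistic sigmoid, softplus, and
reductions — plus a numerically stable softmax cross-entropy.  Gradients
are accumulated by topological-order backpropagation through the recorded
graph; every primitive is validated against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np

__all__ = ["Tensor", "as_tensor", "relu", "sqrt", "square", "sigmoid", "softplus",
           "matmul", "sum_", "mean_", "cross_entropy_logits", "numeric_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A node in the tape: value, accumulated gradient, and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Iterable["Tensor"] = (), backward: Optional[Callable] = None):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- graph traversal --

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Accumulate d(self)/d(leaf) into every reachable leaf's .grad."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:   # iterative DFS; sequences unroll deep graphs
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
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=float), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- primitives --

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g * other.data), other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g / other.data),
                                   other._accum(-g * self.data / other.data**2))
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(x: Tensor) -> Tensor:
    """Halfwave rectification ⌊x⌋ with subgradient 0 at exactly 0."""
    x = as_tensor(x)
    mask = (x.data > 0).astype(float)
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    val = np.sqrt(x.data)
    out = Tensor(val, parents=(x,))
    out._backward = lambda g: x._accum(g * 0.5 / val)
    return out


def square(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(x.data**2, parents=(x,))
    out._backward = lambda g: x._accum(g * 2.0 * x.data)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    val = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out = Tensor(val, parents=(x,))
    out._backward = lambda g: x._accum(g * val * (1.0 - val))
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + eˣ), computed stably; gradient is the logistic sigmoid."""
    x = as_tensor(x)
    val = np.logaddexp(0.0, x.data)
    sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out = Tensor(val, parents=(x,))
    out._backward = lambda g: x._accum(g * sig)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return as_tensor(a) @ as_tensor(b)


def sum_(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(x.data.sum(), parents=(x,))
    out._backward = lambda g: x._accum(np.broadcast_to(g, x.data.shape).copy())
    return out


def mean_(x: Tensor) -> Tensor:
    x = as_tensor(x)
    size = x.data.size
    out = Tensor(x.data.mean(), parents=(x,))
    out._backward = lambda g: x._accum(np.broadcast_to(g / size, x.data.shape).copy())
    return out


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy.  ``logits``: (classes, batch); ``labels``: (batch,) ints."""
    labels = np.asarray(labels, dtype=int)
    z = logits.data
    zmax = z.max(axis=0, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=0, keepdims=True))
    batch = labels.shape[0]
    loss_val = float(np.mean(logsumexp[0] - z[labels, np.arange(batch)]))
    probs = np.exp(z - logsumexp)
    out = Tensor(loss_val, parents=(logits,))

    def bwd(g):
        grad = probs.copy()
        grad[labels, np.arange(batch)] -= 1.0
        logits._accum(g * grad / batch)

    out._backward = bwd
    return out


def numeric_grad(fn: Callable[[np.ndarray], float], x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of a scalar function (test oracle)."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (fn(xp) - fn(xm)) / (2 * eps)
        it.iternext()
    return g
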
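"""A minimal reverse-mode automatic differentiation engine on numpy arrays.

Just enough machinery for the models in this package: dense and sparse
matrix products, gather/scatter for edge-wise message passing, the usual
activations, and a numerically stable binary cross-entropy on logits.
Everything is float64, which keeps finite-difference gradient checks sharp.

Usage::

    w = Tensor(np.zeros((4, 2)), requires_grad=True)
    loss = bce_with_logits(x @ w, y)
    loss.backward()
    w.grad  # dloss/dw
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = np.asarray(grad, dtype=np.float64)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
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
                if p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.value))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.value + other.value, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.value.shape))

        out._backward = bwd
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (other * -1.0)

    def __mul__(self, other) -> "Tensor":
        if np.isscalar(other):
            out = Tensor(self.value * other, parents=(self,))
            out._backward = lambda g: self._accumulate(g * other)
            return out
        other = _as_tensor(other)
        out = Tensor(self.value * other.value, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.value, other.value.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.value / other.value, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.value, self.value.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.value / other.value**2, other.value.shape)
                )

        out._backward = bwd
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.value @ other.value, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.value.T)
            if other.requires_grad:
                other._accumulate(self.value.T @ g)

        out._backward = bwd
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x)


def spmm(matrix: sp.spmatrix, x: Tensor) -> Tensor:
    """Sparse constant matrix times tensor (message aggregation)."""
    matrix = sp.csr_matrix(matrix)
    out = Tensor(matrix @ x.value, parents=(x,))
    out._backward = lambda g: x._accumulate(matrix.T @ g)
    return out


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``x[idx]``; backward scatters gradients back."""
    idx = np.asarray(idx)
    out = Tensor(x.value[idx], parents=(x,))

    def bwd(g):
        acc = np.zeros_like(x.value)
        np.add.at(acc, idx, g)
        x._accumulate(acc)

    out._backward = bwd
    return out


def scatter_add(x: Tensor, idx: np.ndarray, n_rows: int) -> Tensor:
    """Sum edge rows into ``n_rows`` node rows by destination index."""
    idx = np.asarray(idx)
    val = np.zeros((n_rows,) + x.value.shape[1:])
    np.add.at(val, idx, x.value)
    out = Tensor(val, parents=(x,))
    out._backward = lambda g: x._accumulate(g[idx])
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), parents=tensors)
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def _unary(x: Tensor, value: np.ndarray, dvalue: np.ndarray) -> Tensor:
    out = Tensor(value, parents=(x,))
    out._backward = lambda g: x._accumulate(g * dvalue)
    return out


def relu(x: Tensor) -> Tensor:
    return _unary(x, np.maximum(x.value, 0.0), (x.value > 0).astype(np.float64))


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    pos = x.value > 0
    return _unary(
        x,
        np.where(pos, x.value, alpha * x.value),
        np.where(pos, 1.0, alpha),
    )


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.value > 0
    ex = alpha * (np.exp(np.minimum(x.value, 0.0)) - 1.0)
    return _unary(x, np.where(pos, x.value, ex), np.where(pos, 1.0, ex + alpha))


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.value)
    return _unary(x, t, 1.0 - t**2)


def sigmoid(x: Tensor) -> Tensor:
    s = 0.5 * (1.0 + np.tanh(0.5 * x.value))
    return _unary(x, s, s * (1.0 - s))


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.value)
    return _unary(x, e, e)


def mean(x: Tensor) -> Tensor:
    out = Tensor(x.value.mean(), parents=(x,))
    out._backward = lambda g: x._accumulate(np.full_like(x.value, g / x.value.size))
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits, numerically stable.

    ``loss = mean(softplus(z) - y * z)`` with ``softplus(z) = log(1 + e^z)``
    computed without overflow; gradient ``(sigmoid(z) - y) / n``.
    """
    z = logits.value
    y = np.asarray(targets, dtype=np.float64).reshape(z.shape)
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    out = Tensor((softplus - y * z).mean(), parents=(logits,))
    s = 0.5 * (1.0 + np.tanh(0.5 * z))
    out._backward = lambda g: logits._accumulate(g * (s - y) / z.size)
    return out


class Adam:
    """Standard Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    """Glorot/Xavier-uniform initialized parameter tensor."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)
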
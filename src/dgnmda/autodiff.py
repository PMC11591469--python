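"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape of :class:`Tensor` nodes supporting exactly the operations the
dual-encoder model needs: dense matrix products, broadcast arithmetic,
pointwise nonlinearities, row-wise (masked) softmax, layer normalisation,
row gathering, dropout and a numerically stable binary cross-entropy on
logits.  Gradients are accumulated by a topological backward sweep.

The engine is deliberately eager and unfancy; graphs here have a few
hundred nodes, so clarity beats cleverness.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "parameter", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        value: np.ndarray,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
        name: str | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the tape."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS post-order
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float64))

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.value + other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.value.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.value, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.value * other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.value, other.value.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.value @ other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.value.T)
            if other.requires_grad:
                other._accum(self.value.T @ g)

        out._backward = bwd
        return out

    __matmul__ = matmul

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.value.T, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.T)
        return out

    # ---- reductions -------------------------------------------------

    def sum(self) -> "Tensor":
        out = Tensor(self.value.sum(), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(np.full_like(self.value, float(g)))
        return out

    def mean(self) -> "Tensor":
        return self.sum() / self.value.size

    # ---- nonlinearities ---------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.value, 0.0), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (self.value > 0))
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.value > 0, self.value, slope * self.value), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * np.where(self.value > 0, 1.0, slope)
        )
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.value, -500, 500)))
        out = Tensor(s, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * s * (1 - s))
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.value)
        out = Tensor(t, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1 - t * t))
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.value), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * np.sign(self.value))
        return out

    # ---- structured ops ---------------------------------------------

    def concat(self, other: "Tensor", axis: int = 1) -> "Tensor":
        other = self._lift(other)
        out = Tensor(np.concatenate([self.value, other.value], axis=axis), (self, other))
        split = self.value.shape[axis]

        def bwd(g):
            ga, gb = np.split(g, [split], axis=axis)
            if self.requires_grad:
                self._accum(ga)
            if other.requires_grad:
                other._accum(gb)

        out._backward = bwd
        return out

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.value[idx], (self,))

        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.value)
                np.add.at(acc, idx, g)
                self._accum(acc)

        out._backward = bwd
        return out

    def softmax_rows(self, mask: np.ndarray | None = None) -> "Tensor":
        """Row-wise softmax; entries where `mask` is False get zero weight.

        Every row must contain at least one admissible entry.
        """
        z = self.value
        if mask is not None:
            if not mask.any(axis=-1).all():
                raise ValueError("softmax_rows: a row has an empty admissible set")
            z = np.where(mask, z, -np.inf)
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(s, (self,))

        def bwd(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=-1, keepdims=True)
                self._accum(s * (g - dot))

        out._backward = bwd
        return out

    def layer_norm_rows(self, eps: float = 1e-5) -> "Tensor":
        """Normalise each row to zero mean, unit variance (no affine)."""
        mu = self.value.mean(axis=-1, keepdims=True)
        xc = self.value - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        out = Tensor(y, (self,))
        n = self.value.shape[-1]

        def bwd(g):
            if self.requires_grad:
                gm = g.mean(axis=-1, keepdims=True)
                gy = (g * y).mean(axis=-1, keepdims=True)
                self._accum(inv * (g - gm - y * gy))

        out._backward = bwd
        return out

    def dropout(self, p: float, rng: np.random.Generator | None, training: bool) -> "Tensor":
        """Inverted dropout; identity when not training or p == 0."""
        if not training or p <= 0.0:
            return self
        mask = (rng.random(self.value.shape) >= p) / (1.0 - p)
        return self * Tensor(mask)

    def bce_with_logits(self, labels: np.ndarray) -> "Tensor":
        """Mean binary cross-entropy from logits (softplus form, stable)."""
        z = self.value
        y = np.asarray(labels, dtype=np.float64)
        loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
        out = Tensor(loss, (self,))
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

        def bwd(g):
            if self.requires_grad:
                self._accum(float(g) * (p - y) / y.size)

        out._backward = bwd
        return out


def parameter(value: np.ndarray, name: str | None = None) -> Tensor:
    return Tensor(np.asarray(value, dtype=np.float64), requires_grad=True, name=name)


def constant(value: np.ndarray) -> Tensor:
    return Tensor(np.asarray(value, dtype=np.float64))


class Adam:
    """Adam optimizer with decoupled-style L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
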
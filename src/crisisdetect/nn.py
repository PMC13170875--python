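"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical substrate for the joint autoencoder-classifier: a
small tape-based autodiff engine supporting the handful of operations the
model needs (affine layers, ReLU/sigmoid, broadcast arithmetic, reductions,
concatenation) plus an Adam optimizer. Everything is float64 numpy; shapes
are ordinary (batch, features) matrices, so the per-op Python overhead is
negligible next to the BLAS matmuls.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "linear", "relu", "sigmoid", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    Holds a value, an accumulated gradient, and a closure that propagates
    the gradient to its parents. `backward()` runs a topological sweep.
    """

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._backward = None
        self._parents = parents
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # --- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(g, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # --- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            self._accum(g)
            other._accum(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __pow__(self, p: float):
        out = Tensor(self.data**p, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    __matmul__ = matmul

    # --- nonlinearities --------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        # straight-through only inside the interval; zero gradient at the rails
        out = Tensor(np.clip(self.data, lo, hi), (self,))
        mask = (self.data > lo) & (self.data < hi)
        out._backward = lambda g: self._accum(g * mask)
        return out

    # --- reductions & shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --- autodiff driver -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


class Parameter(Tensor):
    """A leaf tensor that optimizers update."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bwd
    return out


def linear(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    return x @ w + b


def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            m_hat = self._m[i] / (1 - self.b1**self.t)
            v_hat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
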
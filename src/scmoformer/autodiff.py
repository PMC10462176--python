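"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: a `Tensor` wraps an ndarray, records
its parents and a backward closure, and `backward()` walks the graph in
reverse topological order.  It supports exactly the operations the model
needs — broadcast arithmetic, dense and sparse-constant matmul, exp / power /
GELU / ReLU, reductions, row-softmax, concatenation and dropout — each with
an analytically exact gradient (verified against central differences in the
test suite).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import ndtr  # standard normal CDF (exact GELU)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), name=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = parents
        self.name = name

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, True, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, True, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, True, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.data.shape))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, True, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(g @ other.data.T)
            if other.requires_grad or other._parents:
                other._accumulate(self.data.T @ g)
        out._backward = bw
        return out

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, True, (self,))
        out._backward = lambda g: self._accumulate(
            g * p * self.data ** (p - 1))
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), True, (self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def t(self) -> "Tensor":
        out = Tensor(self.data.T, True, (self,))
        out._backward = lambda g: self._accumulate(g.T)
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / self.data.size)


# -- free functions --------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), True, (x,))
    out._backward = lambda g: x._accumulate(g * (x.data > 0))
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact GELU ``x * Phi(x)`` with derivative ``Phi(x) + x phi(x)``."""
    Phi = ndtr(x.data)
    out = Tensor(x.data * Phi, True, (x,))
    phi = np.exp(-0.5 * x.data ** 2) / np.sqrt(2 * np.pi)
    out._backward = lambda g: x._accumulate(g * (Phi + x.data * phi))
    return out


def softmax_rows(x: Tensor) -> Tensor:
    """Row-wise softmax; gradient ``p * (g - sum(g*p))`` per row."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(p, True, (x,))

    def bw(g):
        dot = (g * p).sum(axis=-1, keepdims=True)
        x._accumulate(p * (g - dot))
    out._backward = bw
    return out


def spmm(S: sp.spmatrix, x: Tensor) -> Tensor:
    """``S @ x`` with a constant sparse matrix S."""
    S = sp.csr_matrix(S)
    out = Tensor(S @ x.data, True, (x,))
    out._backward = lambda g: x._accumulate(S.T @ g)
    return out


def concat_cols(tensors: list[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1),
                 True, tuple(tensors))
    widths = [t.data.shape[1] for t in tensors]

    def bw(g):
        start = 0
        for t, w in zip(tensors, widths):
            t._accumulate(g[:, start:start + w])
            start += w
    out._backward = bw
    return out


def l2_normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Row normalization ``x / sqrt(|x|^2 + eps)`` as a composite."""
    sq = (x * x).sum(axis=1, keepdims=True)
    norm = (sq + eps).pow(0.5)
    return x / norm


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``p == 0`` or no rng (eval mode)."""
    if p <= 0 or rng is None:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class Adam:
    """Adam with bias correction and optional decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                p.data *= (1.0 - self.lr * self.weight_decay)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
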
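"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the fusion model needs: dense and
sparse-constant matrix products, elementwise transcendental functions
(including ``lgamma`` for count likelihoods), row softmax, reductions,
concatenation, row gathering and numerically-safe clamping.  Gradients
are accumulated in float64; the graph is built eagerly and freed after
``backward``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import sparse as sp
from scipy.special import digamma, gammaln


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        out_data = self.data.T
        return Tensor._make(out_data, (self,), lambda g: (g.T,))

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, k: float):
        return Tensor._make(
            self.data**k, (self,), lambda g: (g * k * self.data ** (k - 1),)
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data @ other.data,
            (self, other),
            lambda g: (g @ other.data.T, self.data.T @ g),
        )

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- backward pass --------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        # `owned` tracks whether a node's grad array is private to it; grads
        # returned by backward closures may alias each other (e.g. both
        # parents of an add receive the same array), so accumulation copies
        # lazily on first +=.
        owned: set[int] = set()
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                g = np.asarray(g, dtype=np.float64)
                if parent.grad is None:
                    parent.grad = g
                elif id(parent) in owned:
                    parent.grad += g
                else:
                    parent.grad = parent.grad + g
                    owned.add(id(parent))
            node._parents = ()
            node._backward = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise functions ----------------------------------------------------

def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)
    return Tensor._make(out_data, (x,), lambda g: (g * out_data,))


def log(x: Tensor) -> Tensor:
    return Tensor._make(np.log(x.data), (x,), lambda g: (g / x.data,))


def log1p(x: Tensor) -> Tensor:
    return Tensor._make(np.log1p(x.data), (x,), lambda g: (g / (1.0 + x.data),))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._make(s, (x,), lambda g: (g * s * (1.0 - s),))


def softplus(x: Tensor) -> Tensor:
    out_data = np.logaddexp(0.0, x.data)
    return Tensor._make(out_data, (x,), lambda g: (g / (1.0 + np.exp(-x.data)),))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._make(np.where(mask, x.data, 0.0), (x,), lambda g: (g * mask,))


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    mask = x.data > 0
    neg = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)
    out_data = np.where(mask, x.data, neg)
    return Tensor._make(
        out_data, (x,), lambda g: (g * np.where(mask, 1.0, neg + alpha),)
    )


def lgamma(x: Tensor) -> Tensor:
    return Tensor._make(gammaln(x.data), (x,), lambda g: (g * digamma(x.data),))


def clamp(x: Tensor, lo: float | None = None, hi: float | None = None) -> Tensor:
    out_data = np.clip(x.data, lo, hi)
    inside = np.ones_like(x.data, dtype=bool)
    if lo is not None:
        inside &= x.data >= lo
    if hi is not None:
        inside &= x.data <= hi
    return Tensor._make(out_data, (x,), lambda g: (g * inside,))


def logaddexp(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.logaddexp(a.data, b.data)
    wa = 1.0 / (1.0 + np.exp(b.data - a.data))

    def backward(g):
        return (
            _unbroadcast(g * wa, a.shape),
            _unbroadcast(g * (1.0 - wa), b.shape),
        )

    return Tensor._make(out_data, (a, b), backward)


def where(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select from `a` where boolean `mask` holds, else `b`; mask is constant."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.where(mask, a.data, b.data)

    def backward(g):
        return (
            _unbroadcast(np.where(mask, g, 0.0), a.shape),
            _unbroadcast(np.where(mask, 0.0, g), b.shape),
        )

    return Tensor._make(out_data, (a, b), backward)


# -- structural ops ----------------------------------------------------------

def spmm(A: sp.spmatrix, x: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a dense tensor."""
    A = sp.csr_matrix(A)
    return Tensor._make(A @ x.data, (x,), lambda g: (A.T @ g,))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)

    def backward(g):
        out = np.zeros_like(x.data)
        np.add.at(out, idx, g)
        return (out,)

    return Tensor._make(x.data[idx], (x,), backward)


def row_softmax(x: Tensor) -> Tensor:
    """Numerically-stabilized softmax along the last axis."""
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=-1, keepdims=True)
        return (s * (g - dot),)

    return Tensor._make(s, (x,), backward)


def row_log_softmax(x: Tensor) -> Tensor:
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    out_data = shifted - lse
    s = np.exp(out_data)

    def backward(g):
        return (g - s * g.sum(axis=-1, keepdims=True),)

    return Tensor._make(out_data, (x,), backward)


# -- parameters and optimisation ----------------------------------------------

class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Adam:
    """Adam with the standard bias correction; float64 state."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
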
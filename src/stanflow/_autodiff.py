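"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the attention encoder and the conditional
flow need: broadcasting arithmetic, (batched) matmul, slicing,
concatenation, the usual pointwise nonlinearities, reductions, hard
clamping, and simplex maps (softmax / sparsemax) with analytic Jacobians.
Gradient correctness is enforced by finite-difference tests.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Tensor", "concat", "sparsemax_np", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def sparsemax_np(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Euclidean projection of ``z`` onto the probability simplex (sort-threshold)."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape[axis] == 0:
        raise ValueError("sparsemax of an empty vector is undefined")
    z = np.moveaxis(z, axis, -1)
    zs = -np.sort(-z, axis=-1)  # descending
    k = np.arange(1, z.shape[-1] + 1, dtype=np.float64)
    cs = np.cumsum(zs, axis=-1)
    support = 1.0 + k * zs > cs
    k_z = support.sum(axis=-1, keepdims=True)  # size of the support set
    cs_k = np.take_along_axis(cs, k_z - 1, axis=-1)
    tau = (cs_k - 1.0) / k_z
    out = np.maximum(z - tau, 0.0)
    return np.moveaxis(out, -1, axis)


class Tensor:
    """Array node of the computation tape."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._backward = None
        self._parents = tuple(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._parents)

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(np.asarray(grad), self.data.shape)

    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            self._accum(g)
            other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, (self, other))

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        out._backward = bw
        return out

    def __pow__(self, e):
        assert np.isscalar(e)
        out = Tensor(self.data**e, (self,))
        out._backward = lambda g: self._accum(g * e * self.data ** (e - 1))
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.expand_dims(g, -1) * b
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.expand_dims(a, -1) * g
            self._accum(_unbroadcast(np.asarray(ga), a.shape))
            other._accum(_unbroadcast(np.asarray(gb), b.shape))

        out._backward = bw
        return out

    # -- pointwise --------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), (self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def clamp(self, lo, hi):
        out = Tensor(np.clip(self.data, lo, hi), (self,))
        mask = (self.data >= lo) & (self.data <= hi)
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(np.asarray(g).reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, idx, g)

        out._backward = bw
        return out

    # -- simplex maps -----------------------------------------------------
    def softmax(self):
        """Softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        out = Tensor(e / e.sum(axis=-1, keepdims=True), (self,))

        def bw(g):
            s = out.data
            self._accum(s * (g - (g * s).sum(axis=-1, keepdims=True)))

        out._backward = bw
        return out

    def sparsemax(self):
        """Sparsemax (simplex projection) over the last axis."""
        out = Tensor(sparsemax_np(self.data, axis=-1), (self,))

        def bw(g):
            supp = out.data > 0
            k = supp.sum(axis=-1, keepdims=True)
            mean_g = (g * supp).sum(axis=-1, keepdims=True) / np.maximum(k, 1)
            self._accum(supp * (g - mean_g))

        out._backward = bw
        return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(np.asarray(g), splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr=1e-3, betas=(0.9, 0.999), eps=1e-8, lrs=None):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.lrs = list(lrs) if lrs is not None else [lr] * len(self.params)
        if len(self.lrs) != len(self.params):
            raise ValueError("lrs must match params")
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

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
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lrs[i] * mh / (np.sqrt(vh) + self.eps)
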
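"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the graph encoders need: broadcasting
add/mul, dense matmul, constant-sparse @ variable-dense products, ReLU
family, exp/log, constant powers, reductions, row gather/scatter and
segment sums (for attention softmax). Gradients are checked against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor(self.data + other.data,
                      self.requires_grad or other.requires_grad,
                      (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, self.requires_grad, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor(self.data * other.data,
                      self.requires_grad or other.requires_grad,
                      (self, other), bw)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data,
                      self.requires_grad or other.requires_grad,
                      (self, other), bw)

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(out, self.requires_grad, (self,), bw)

    def mean(self):
        n = self.data.size
        return self.sum() * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0

    def bw(g):
        t._accum(g * mask)

    return Tensor(t.data * mask, t.requires_grad, (t,), bw)


def leaky_relu(t: Tensor, slope: float = 0.2) -> Tensor:
    mask = t.data > 0
    scale = np.where(mask, 1.0, slope)

    def bw(g):
        t._accum(g * scale)

    return Tensor(t.data * scale, t.requires_grad, (t,), bw)


def exp(t: Tensor) -> Tensor:
    out = np.exp(t.data)

    def bw(g):
        t._accum(g * out)

    return Tensor(out, t.requires_grad, (t,), bw)


def log(t: Tensor, eps: float = 0.0) -> Tensor:
    d = t.data + eps

    def bw(g):
        t._accum(g / d)

    return Tensor(np.log(d), t.requires_grad, (t,), bw)


def pow_const(t: Tensor, p: float) -> Tensor:
    out = np.power(t.data, p)

    def bw(g):
        t._accum(g * p * np.power(t.data, p - 1.0))

    return Tensor(out, t.requires_grad, (t,), bw)


def spmm(mat: sp.spmatrix, t: Tensor, matT=None) -> Tensor:
    """Constant sparse matrix times variable dense tensor.

    Pass a precomputed ``matT`` (CSR transpose) when calling repeatedly.
    """
    if matT is None:
        matT = mat.T.tocsr()

    def bw(g):
        t._accum(matT @ g)

    return Tensor(mat @ t.data, t.requires_grad, (t,), bw)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  any(t.requires_grad for t in tensors), tuple(tensors), bw)


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)

    def bw(g):
        acc = np.zeros_like(t.data)
        np.add.at(acc, idx, g)
        t._accum(acc)

    return Tensor(t.data[idx], t.requires_grad, (t,), bw)


def segment_sum(t: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    seg = np.asarray(seg)
    out = np.zeros((n_segments,) + t.data.shape[1:])
    np.add.at(out, seg, t.data)

    def bw(g):
        t._accum(g[seg])

    return Tensor(out, t.requires_grad, (t,), bw)


def log_softmax(t: Tensor) -> Tensor:
    """Row-wise log-softmax with analytic Jacobian-vector product."""
    z = t.data - t.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    out = z - lse
    soft = np.exp(out)

    def bw(g):
        t._accum(g - soft * g.sum(axis=1, keepdims=True))

    return Tensor(out, t.requires_grad, (t,), bw)


class Adam:
    """Adaptive-moment gradient descent over a list of Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=(fan_in, fan_out)),
                  requires_grad=True)


def zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)
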
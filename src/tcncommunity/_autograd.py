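"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine covering exactly the operations the
soft-assignment model needs: dense matrix products, products with a
fixed sparse adjacency, elementwise arithmetic with broadcasting, ReLU,
row-wise softmax, log/sqrt and reductions.  The working precision is
float64 by default and switchable (training uses float32).  An Adam
optimizer over parameter tensors is included.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "constant", "parameter", "spmm", "Adam", "default_dtype"]

_DTYPE = np.float64


@contextmanager
def default_dtype(dtype):
    """Temporarily switch the tape's working precision (e.g. float32 training)."""
    global _DTYPE
    old = _DTYPE
    _DTYPE = dtype
    try:
        yield
    finally:
        _DTYPE = old


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value: np.ndarray,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
        requires_grad: bool = False,
    ):
        self.value = np.asarray(value, dtype=_DTYPE)
        self.grad: Optional[np.ndarray] = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def _accum(self, g: np.ndarray) -> None:
        # out-of-place accumulation: safe for read-only broadcast views and
        # for buffers shared between siblings, and avoids per-node copies
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(1.0, dtype=_DTYPE)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), constant(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, constant(-1.0)))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return mul(self, constant(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))


def constant(value) -> Tensor:
    return Tensor(np.asarray(value, dtype=_DTYPE))


def parameter(value) -> Tensor:
    return Tensor(np.asarray(value, dtype=_DTYPE), requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient g back to the broadcast-source shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value + b.value

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.value.shape))

    return Tensor(out_val, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value * b.value

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.value, a.value.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.value, b.value.shape))

    return Tensor(out_val, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value / b.value

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.value, a.value.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.value / (b.value ** 2), b.value.shape))

    return Tensor(out_val, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value @ b.value

    def backward(g):
        if a.requires_grad:
            a._accum(g @ b.value.T)
        if b.requires_grad:
            b._accum(a.value.T @ g)

    return Tensor(out_val, (a, b), backward)


def transpose(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accum(g.T)

    return Tensor(a.value.T, (a,), backward)


def spmm(A: sp.spmatrix, x: Tensor, AT: Optional[sp.spmatrix] = None) -> Tensor:
    """Product of a fixed (non-differentiated) sparse matrix with x.

    Pass ``AT=A`` for symmetric matrices to avoid a transpose per call.
    """
    A = A.tocsr()
    out_val = A @ x.value

    def backward(g):
        if x.requires_grad:
            At = A.T.tocsr() if AT is None else AT
            x._accum(At @ g)

    return Tensor(out_val, (x,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.value > 0
    out_val = a.value * mask

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return Tensor(out_val, (a,), backward)


def row_softmax(a: Tensor) -> Tensor:
    """Numerically stable softmax along the last axis."""
    z = a.value - a.value.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out_val = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_val).sum(axis=-1, keepdims=True)
            a._accum(out_val * (g - dot))

    return Tensor(out_val, (a,), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_val = a.value.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if axis is None:
                a._accum(np.broadcast_to(g, a.value.shape))
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g2, a.value.shape))

    return Tensor(out_val, (a,), backward)


def mean_rows(a: Tensor) -> Tensor:
    """Mean over axis 0 (rows), returning a vector."""
    n = a.value.shape[0]
    out_val = a.value.mean(axis=0)

    def backward(g):
        if a.requires_grad:
            a._accum(np.broadcast_to(g / n, a.value.shape))

    return Tensor(out_val, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    out_val = np.sqrt(a.value)

    def backward(g):
        if a.requires_grad:
            a._accum(g / (2.0 * out_val))

    return Tensor(out_val, (a,), backward)


def log(a: Tensor) -> Tensor:
    out_val = np.log(a.value)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.value)

    return Tensor(out_val, (a,), backward)


def fro_norm(a: Tensor) -> Tensor:
    """Frobenius norm as a scalar tensor."""
    return sqrt(tsum(mul(a, a)))


def cross_entropy_logits(logits: Tensor, label: int) -> Tensor:
    """-log softmax(logits)[label] via log-sum-exp; stable for saturated logits."""
    z = logits.value.ravel()
    zmax = z.max()
    lse = zmax + np.log(np.sum(np.exp(z - zmax)))
    out_val = np.asarray(lse - z[label])
    p = np.exp(z - lse)

    def backward(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[label] -= 1.0
            logits._accum(float(g) * grad.reshape(logits.value.shape))

    return Tensor(out_val, (logits,), backward)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
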
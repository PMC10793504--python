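"""Reverse-mode automatic differentiation on numpy arrays.

This is the compute backend for the segmentation network: a small dynamic
graph of :class:`Tensor` nodes, each remembering its parents and a closure
that maps the output gradient to each parent's gradient.  Only the
operations the shifted-window architecture needs are implemented (batched
matmul, reshape/transpose, concatenation, slicing, toroidal roll, softmax,
layer normalisation, GELU, gather, reductions and a fused softmax
cross-entropy).  Gradients are checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "concat",
    "matmul",
    "softmax",
    "layer_norm",
    "gelu",
    "relu",
    "gather",
    "cross_entropy",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fns")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, np.ndarray):
            self.data = data
        elif isinstance(data, np.generic):  # numpy scalar: keep its dtype
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._grad_fns: tuple[Callable[[np.ndarray], np.ndarray], ...] = ()

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], grad_fns) -> "Tensor":
        out = Tensor(data)
        tracked = [(p, fn) for p, fn in zip(parents, grad_fns) if p.requires_grad]
        if tracked:
            out.requires_grad = True
            out._parents = tuple(p for p, _ in tracked)
            out._grad_fns = tuple(fn for _, fn in tracked)
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients into every reachable ``requires_grad`` leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion overflows on deep graphs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, fn in zip(node._parents, node._grad_fns):
                pg = fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # leaves with parents==() handled above; interior requires_grad leaves
        # (e.g. detached heads) do not occur in this package

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other, self.dtype)
        data = self.data + other.data
        return Tensor._make(
            data,
            (self, other),
            (
                lambda g: _unbroadcast(g, self.data.shape),
                lambda g: _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __sub__(self, other) -> "Tensor":
        other = _as_tensor(other, self.dtype)
        data = self.data - other.data
        return Tensor._make(
            data,
            (self, other),
            (
                lambda g: _unbroadcast(g, self.data.shape),
                lambda g: _unbroadcast(-g, other.data.shape),
            ),
        )

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other, self.dtype)
        data = self.data * other.data
        return Tensor._make(
            data,
            (self, other),
            (
                lambda g: _unbroadcast(g * other.data, self.data.shape),
                lambda g: _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Tensor":
        inv = 1.0 / float(scalar)
        return self * inv

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __matmul__(self, other) -> "Tensor":
        return matmul(self, other)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), (lambda g: g.reshape(old),)
        )

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            np.transpose(self.data, axes),
            (self,),
            (lambda g: np.transpose(g, inv),),
        )

    def roll(self, shifts, axes) -> "Tensor":
        neg = tuple(-s for s in shifts) if isinstance(shifts, (tuple, list)) else -shifts
        return Tensor._make(
            np.roll(self.data, shifts, axis=axes),
            (self,),
            (lambda g: np.roll(g, neg, axis=axes),),
        )

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]
        shape = self.data.shape
        dtype = self.data.dtype

        def grad_fn(g, idx=idx, shape=shape, dtype=dtype):
            out = np.zeros(shape, dtype=dtype)
            np.add.at(out, idx, g)
            return out

        return Tensor._make(data, (self,), (grad_fn,))

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def grad_fn(g, axis=axis, keepdims=keepdims, shape=shape):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).copy()

        return Tensor._make(data, (self,), (grad_fn,))

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    data = np.matmul(a.data, b.data)

    def grad_a(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        return _unbroadcast(ga, a.data.shape)

    def grad_b(g):
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(gb, b.data.shape)

    return Tensor._make(data, (a, b), (grad_a, grad_b))


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_fn(i):
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor._make(data, tuple(tensors), tuple(make_fn(i) for i in range(len(tensors))))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def grad_fn(g):
        return y * (g - (g * y).sum(axis=axis, keepdims=True))

    return Tensor._make(y, (x,), (grad_fn,))


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    data = xhat * weight.data + bias.data
    n = x.data.shape[-1]

    def grad_x(g):
        gh = g * weight.data
        return inv * (gh - gh.mean(axis=-1, keepdims=True) - xhat * (gh * xhat).mean(axis=-1, keepdims=True))

    def grad_w(g):
        return _unbroadcast(g * xhat, weight.data.shape)

    def grad_b(g):
        return _unbroadcast(g, bias.data.shape)

    return Tensor._make(data, (x, weight, bias), (grad_x, grad_w, grad_b))


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    phi = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    data = x.data * phi

    def grad_fn(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data * x.data)
        return g * (phi + x.data * pdf)

    return Tensor._make(data.astype(x.data.dtype), (x,), (grad_fn,))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._make(x.data * mask, (x,), (lambda g: g * mask,))


def gather(table: Tensor, index: np.ndarray) -> Tensor:
    """Index the first axis of ``table`` with an integer array.

    Used for relative-position bias lookup; gradients scatter-add back
    into the table.
    """
    data = table.data[index]
    shape = table.data.shape
    dtype = table.data.dtype

    def grad_fn(g):
        out = np.zeros(shape, dtype=dtype)
        np.add.at(out, index, g)
        return out

    return Tensor._make(data, (table,), (grad_fn,))


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy.

    ``logits`` has shape (N, K); ``targets`` is an int array of shape (N,).
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    n = targets.shape[0]
    nll = -logp[np.arange(n), targets].mean()

    def grad_fn(g):
        p = np.exp(logp)
        p[np.arange(n), targets] -= 1.0
        return (g * p / n).astype(logits.data.dtype)

    out = Tensor._make(np.asarray(nll, dtype=logits.data.dtype), (logits,), (grad_fn,))
    return out
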
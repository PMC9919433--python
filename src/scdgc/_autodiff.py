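"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the network forward pass and its losses
need: broadcasting arithmetic, 2-D matrix products, per-channel affine maps
on ``batch x nodes x channels`` arrays, graph propagation with a fixed
propagation matrix, ReLU, log-softmax, reductions, reshape/concat, and a
few small-vector helpers for the attention scorer.  Gradients flow to every
`Tensor` created with ``requires_grad=True`` — model parameters during
training, and the perturbation direction during the virtual-adversarial
power iteration.

All data is float64.  The graph is built eagerly; ``Tensor.backward`` runs
a single reverse topological sweep and accumulates ``.grad`` on leaves.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjp = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph execution -----------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this scalar into all requiring leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor], vjp) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / broadcasting
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def relu(x) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return _node(np.where(mask, x.data, 0.0), (x,), lambda g: (g * mask,))


def exp(x) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)
    return _node(out, (x,), lambda g: (g * out,))


def log(x, floor: float = 1e-12) -> Tensor:
    """Clamped natural log: values below `floor` are treated as `floor`."""
    x = as_tensor(x)
    clipped = np.maximum(x.data, floor)
    mask = x.data >= floor
    return _node(np.log(clipped), (x,), lambda g: (g * mask / clipped,))


def square(x) -> Tensor:
    x = as_tensor(x)
    return _node(x.data**2, (x,), lambda g: (2.0 * g * x.data,))


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    """2-D matrix product."""
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError(f"matmul expects 2-D operands, got {a.shape} @ {b.shape}")
    return _node(
        a.data @ b.data,
        (a, b),
        lambda g: (g @ b.data.T, a.data.T @ g),
    )


def affine(x, w, b) -> Tensor:
    """x @ w + b for a 2-D batch x features input."""
    return add(matmul(x, w), b)


def channel_affine(h, w, b) -> Tensor:
    """Per-node channel map: out[b,m,o] = sum_i h[b,m,i] w[i,o] + b[o]."""
    h, w, b = as_tensor(h), as_tensor(w), as_tensor(b)
    out = np.einsum("bmi,io->bmo", h.data, w.data, optimize=True) + b.data

    def vjp(g):
        gh = np.einsum("bmo,io->bmi", g, w.data, optimize=True)
        gw = np.einsum("bmi,bmo->io", h.data, g, optimize=True)
        gb = g.sum(axis=(0, 1))
        return gh, gw, gb

    return _node(out, (h, w, b), vjp)


def propagate(p_matrix: np.ndarray, h) -> Tensor:
    """Graph propagation out[b,i,c] = sum_j P[i,j] h[b,j,c]; P is constant."""
    h = as_tensor(h)
    p_matrix = np.asarray(p_matrix, dtype=np.float64)
    out = np.einsum("ij,bjc->bic", p_matrix, h.data, optimize=True)

    def vjp(g):
        return (np.einsum("ij,bic->bjc", p_matrix, g, optimize=True),)

    return _node(out, (h,), vjp)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def sum_(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, x.shape).copy(),)

    return _node(out, (x,), vjp)


def mean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    count = x.data.size if axis is None else np.prod(
        [x.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(x, axis=axis, keepdims=keepdims), 1.0 / float(count))


def max_axis(x, axis: int) -> Tensor:
    """Max over one axis; gradient routes to the first arg-max (tie-break)."""
    x = as_tensor(x)
    idx = np.argmax(x.data, axis=axis)
    out = np.take_along_axis(x.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis)

    def vjp(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(
            gx, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
        )
        return (gx,)

    return _node(out, (x,), vjp)


def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    old = x.shape
    return _node(x.data.reshape(shape), (x,), lambda g: (g.reshape(old),))


def concat(tensors: Iterable, axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]
    return _node(
        np.concatenate([t.data for t in ts], axis=axis),
        ts,
        lambda g: tuple(np.split(g, splits, axis=axis)),
    )


# ---------------------------------------------------------------------------
# softmax family and small-vector helpers
# ---------------------------------------------------------------------------

def log_softmax(z) -> Tensor:
    """Row-wise log-softmax of a 2-D logits array."""
    z = as_tensor(z)
    shifted = z.data - z.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    out = shifted - lse
    soft = np.exp(out)

    def vjp(g):
        return (g - soft * g.sum(axis=1, keepdims=True),)

    return _node(out, (z,), vjp)


def softmax1d(v) -> Tensor:
    """Softmax of a 1-D score vector (attention weights)."""
    v = as_tensor(v)
    shifted = v.data - v.data.max()
    e = np.exp(shifted)
    p = e / e.sum()

    def vjp(g):
        return (p * (g - float(g @ p)),)

    return _node(p, (v,), vjp)


def stack_scalars(scalars: Sequence) -> Tensor:
    ts = [as_tensor(s) for s in scalars]
    out = np.array([float(t.data) for t in ts])

    def vjp(g):
        return tuple(np.asarray(g[i]) for i in range(len(ts)))

    return _node(out, ts, vjp)


def index(vec, i: int) -> Tensor:
    vec = as_tensor(vec)

    def vjp(g):
        gv = np.zeros_like(vec.data)
        gv[i] = g
        return (gv,)

    return _node(vec.data[i], (vec,), vjp)


def dot(a, b) -> Tensor:
    """Inner product of two 1-D vectors."""
    return sum_(mul(a, b))


def matvec(w, v) -> Tensor:
    """2-D matrix times 1-D vector."""
    w, v = as_tensor(w), as_tensor(v)
    return reshape(matmul(w, reshape(v, (-1, 1))), (w.shape[0],))
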
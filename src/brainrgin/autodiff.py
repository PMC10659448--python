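"""Reverse-mode automatic differentiation over NumPy float64 arrays.

The network in this package is a short pipeline of dense linear algebra on
small batched tensors (at most a few hundred graphs x 53 nodes x 256
channels), so a compact tape-based engine is sufficient and keeps every
run bit-deterministic.  Each operation records its parent tensors and a
closure that maps the output gradient to parent gradients; ``backward``
walks the tape in reverse topological order.

Conventions
-----------
* every :class:`Tensor` wraps a ``float64`` ndarray; scalars are 0-d arrays
* gradients accumulate into ``Tensor.grad`` (an ndarray) after calling
  ``backward()`` on a scalar-valued tensor
* index arguments (gather indices, argsorts, branch masks) are constants
  of the tape — the standard subgradient treatment of piecewise selection
* broadcasting follows NumPy; gradients are summed back over broadcast
  axes
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "parameter",
    "add",
    "mul",
    "div",
    "matmul",
    "einsum",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "sqrt",
    "absolute",
    "clip",
    "tsum",
    "tmean",
    "amax",
    "concatenate",
    "reshape",
    "swapaxes",
    "take",
    "take_along",
]


class Tensor:
    """An ndarray plus the tape bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    # -- array-like sugar -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(astensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    # -- autodiff ---------------------------------------------------------
    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float64)

        # iterative post-order DFS -> topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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

        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                g = np.asarray(g, dtype=np.float64)
                parent.grad = g if parent.grad is None else parent.grad + g


def astensor(x) -> Tensor:
    """Wrap ``x`` in a constant :class:`Tensor` (no-op if already one)."""
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    """A tensor flagged as trainable."""
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def _op(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` back down to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- arithmetic -----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _op(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _op(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)),
    )


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _op(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.data, a.shape),
            _unbroadcast(-g * a.data / (b.data * b.data), b.shape),
        ),
    )


def power(a, p: float) -> Tensor:
    a = astensor(a)
    p = float(p)
    return _op(a.data**p, (a,), lambda g: (g * p * a.data ** (p - 1.0),))


def matmul(a, b) -> Tensor:
    """Batched matrix product; both operands must be at least 2-d."""
    a, b = astensor(a), astensor(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires >=2-d operands; use einsum for vectors")

    def backward(g):
        if a.ndim > 2 and b.ndim == 2:
            # shared right-hand matrix: fold the batch axes into one BLAS
            # call instead of materialising per-batch weight gradients
            ga = g @ b.data.T
            gb = a.data.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1])
            return ga, gb
        ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
        gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape)
        return ga, gb

    return _op(a.data @ b.data, (a, b), backward)


def einsum(subscripts: str, *operands) -> Tensor:
    """``np.einsum`` with gradients.

    Requires an explicit ``->`` output and, for gradient support, every
    index of each operand must appear in the output or another operand
    (true for contractions; not for single-operand reductions — use
    :func:`tsum` for those).
    """
    if "->" not in subscripts:
        raise ValueError("einsum spec must contain '->'")
    in_spec, out_spec = subscripts.split("->")
    in_subs = [s.strip() for s in in_spec.split(",")]
    tensors = [astensor(t) for t in operands]
    if len(in_subs) != len(tensors):
        raise ValueError("operand count does not match einsum spec")
    data = np.einsum(subscripts, *[t.data for t in tensors], optimize=True)

    def backward(g):
        grads = []
        for i, sub in enumerate(in_subs):
            others = [s for j, s in enumerate(in_subs) if j != i]
            available = set(out_spec) | set("".join(others))
            if not set(sub) <= available:
                raise ValueError(
                    f"einsum gradient undefined for operand '{sub}' in '{subscripts}'"
                )
            spec = ",".join([out_spec] + others) + "->" + sub
            arrays = [g] + [t.data for j, t in enumerate(tensors) if j != i]
            grads.append(np.einsum(spec, *arrays, optimize=True))
        return grads

    return _op(data, tensors, backward)


# -- elementwise nonlinearities -------------------------------------------

def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    return _op(np.where(mask, a.data, 0.0), (a,), lambda g: (g * mask,))


def sigmoid(a) -> Tensor:
    a = astensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    return _op(s, (a,), lambda g: (g * s * (1.0 - s),))


def exp(a) -> Tensor:
    a = astensor(a)
    e = np.exp(a.data)
    return _op(e, (a,), lambda g: (g * e,))


def log(a) -> Tensor:
    a = astensor(a)
    return _op(np.log(a.data), (a,), lambda g: (g / a.data,))


def sqrt(a) -> Tensor:
    a = astensor(a)
    r = np.sqrt(a.data)
    return _op(r, (a,), lambda g: (g * 0.5 / r,))


def absolute(a) -> Tensor:
    a = astensor(a)
    return _op(np.abs(a.data), (a,), lambda g: (g * np.sign(a.data),))


def clip(a, lo: float, hi: float) -> Tensor:
    a = astensor(a)
    mask = (a.data >= lo) & (a.data <= hi)
    return _op(np.clip(a.data, lo, hi), (a,), lambda g: (g * mask,))


# -- reductions -----------------------------------------------------------

def _expand_reduced(g: np.ndarray, shape, axis, keepdims) -> np.ndarray:
    if axis is None:
        return np.broadcast_to(g, shape).copy()
    axes = (axis,) if np.isscalar(axis) else tuple(axis)
    axes = tuple(a % len(shape) for a in axes)
    if not keepdims:
        for a in sorted(axes):
            g = np.expand_dims(g, a)
    return np.broadcast_to(g, shape).copy()


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    return _op(
        a.data.sum(axis=axis, keepdims=keepdims),
        (a,),
        lambda g: (_expand_reduced(g, a.shape, axis, keepdims),),
    )


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    data = a.data.mean(axis=axis, keepdims=keepdims)
    if axis is None:
        count = a.data.size
    else:
        axes = (axis,) if np.isscalar(axis) else tuple(axis)
        count = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return _op(
        data,
        (a,),
        lambda g: (_expand_reduced(g, a.shape, axis, keepdims) / count,),
    )


def amax(a, axis: int, keepdims=False) -> Tensor:
    """Maximum along one axis; ties route the gradient to the first hit."""
    a = astensor(a)
    data = a.data.max(axis=axis, keepdims=keepdims)
    idx = np.expand_dims(a.data.argmax(axis=axis), axis)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        out = np.zeros_like(a.data)
        np.put_along_axis(out, idx, g, axis)
        return (out,)

    return _op(data, (a,), backward)


# -- shape & indexing -----------------------------------------------------

def concatenate(tensors: Iterable, axis: int = -1) -> Tensor:
    ts = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]
    return _op(
        np.concatenate([t.data for t in ts], axis=axis),
        ts,
        lambda g: tuple(np.split(g, splits, axis=axis)),
    )


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    return _op(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = astensor(a)
    return _op(np.swapaxes(a.data, ax1, ax2), (a,), lambda g: (np.swapaxes(g, ax1, ax2),))


def getitem(a, key) -> Tensor:
    a = astensor(a)

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, key, g)
        return (out,)

    return _op(a.data[key], (a,), backward)


def take(a, indices) -> Tensor:
    """Gather rows along axis 0 with an arbitrary integer index array."""
    a = astensor(a)
    idx = np.asarray(indices)

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, idx, g)
        return (out,)

    return _op(a.data[idx], (a,), backward)


def take_along(a, indices, axis: int) -> Tensor:
    """Differentiable ``np.take_along_axis`` (indices are constants)."""
    a = astensor(a)
    idx = np.asarray(indices)
    data = np.take_along_axis(a.data, idx, axis=axis)

    def backward(g):
        out = np.zeros_like(a.data)
        grids = list(np.indices(g.shape, sparse=False))
        grids[axis] = np.broadcast_to(idx, g.shape)
        np.add.at(out, tuple(grids), g)
        return (out,)

    return _op(data, (a,), backward)
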
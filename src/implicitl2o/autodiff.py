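"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implicit models are trained by backpropagating through a *single* application
of the iteration map at an approximate fixed point (Jacobian-free
backpropagation).  Only a handful of primitives appear in that one step —
linear maps, soft-thresholding, clamps, ball projections, tanh — so a small
tape suffices.  Keeping the tape in-package also makes the memory contract
directly observable: :func:`graph_size` counts the nodes of the derivative
graph, which must stay constant as the (untracked) fixed-point phase deepens.

Constants are plain ``numpy`` arrays and never enter the graph; only
:class:`Tensor` leaves created with ``requires_grad=True`` accumulate ``grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "param",
    "constant",
    "add",
    "sub",
    "scale",
    "matvec",
    "matvec_t",
    "tanh",
    "shrink_op",
    "clamp_op",
    "ball_project_op",
    "mse",
    "backward",
    "graph_size",
]


class Tensor:
    """A node in the derivative graph.

    Parameters
    ----------
    value : array_like
        The numeric payload.
    parents : tuple of (Tensor, callable)
        Each callable maps the incoming cotangent to this parent's cotangent.
    requires_grad : bool
        Leaf flag; gradients are accumulated into ``grad`` during backward.
    """

    __slots__ = ("value", "parents", "requires_grad", "grad")

    def __init__(self, value, parents=(), requires_grad=False):
        self.value = np.asarray(value, dtype=float)
        self.parents = tuple(parents)
        self.requires_grad = bool(requires_grad)
        self.grad = None

    @property
    def shape(self):
        return self.value.shape

    # Convenience arithmetic; non-Tensor operands are treated as constants.
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return scale(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return scale(self, -1.0)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.value.shape}, leaf={self.requires_grad})"


def param(value):
    """A trainable leaf."""
    return Tensor(value, requires_grad=True)


def constant(value):
    """A non-trainable node (rarely needed; plain arrays usually suffice)."""
    return Tensor(value)


def _val(x):
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    g = np.asarray(g, dtype=float)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def _binary(a, b, value, vjp_a, vjp_b):
    parents = []
    if isinstance(a, Tensor):
        parents.append((a, vjp_a))
    if isinstance(b, Tensor):
        parents.append((b, vjp_b))
    if not parents:
        return value
    return Tensor(value, parents)


def add(a, b):
    av, bv = _val(a), _val(b)
    return _binary(
        a, b, av + bv,
        lambda g: _unbroadcast(g, av.shape),
        lambda g: _unbroadcast(g, bv.shape),
    )


def sub(a, b):
    av, bv = _val(a), _val(b)
    return _binary(
        a, b, av - bv,
        lambda g: _unbroadcast(g, av.shape),
        lambda g: _unbroadcast(-g, bv.shape),
    )


def scale(a, b):
    """Elementwise (or scalar) product."""
    av, bv = _val(a), _val(b)
    return _binary(
        a, b, av * bv,
        lambda g: _unbroadcast(g * bv, av.shape),
        lambda g: _unbroadcast(g * av, bv.shape),
    )


def matvec(mat, x):
    """``mat @ x`` with ``mat`` a 2-d array/Tensor and ``x`` a vector or
    column-stacked batch."""
    mv, xv = _val(mat), _val(x)
    out = mv @ xv

    def vjp_mat(g):
        if xv.ndim == 1:
            return np.outer(g, xv)
        return g @ xv.T

    def vjp_x(g):
        return mv.T @ g

    return _binary(mat, x, out, vjp_mat, vjp_x)


def matvec_t(mat, x):
    """``mat.T @ x`` (adjoint application) differentiable in both arguments."""
    mv, xv = _val(mat), _val(x)
    out = mv.T @ xv

    def vjp_mat(g):
        if xv.ndim == 1:
            return np.outer(xv, g)
        return xv @ g.T

    def vjp_x(g):
        return mv @ g

    return _binary(mat, x, out, vjp_mat, vjp_x)


def tanh(x):
    xv = _val(x)
    out = np.tanh(xv)
    if not isinstance(x, Tensor):
        return out
    return Tensor(out, [(x, lambda g, out=out: g * (1.0 - out * out))])


def shrink_op(x, theta):
    """Soft-threshold ``sign(x) * max(|x| - theta, 0)``.

    Differentiable in ``x`` (a.e. derivative ``1_{|x|>theta}``) and in the
    scalar ``theta`` (a.e. derivative ``-sign(x) 1_{|x|>theta}``).
    """
    xv, tv = _val(x), float(_val(theta))
    mask = np.abs(xv) > tv
    out = np.sign(xv) * np.maximum(np.abs(xv) - tv, 0.0)

    def vjp_x(g):
        return g * mask

    def vjp_theta(g):
        return np.asarray(-np.sum(g * np.sign(xv) * mask))

    return _binary(x, theta, out, vjp_x, vjp_theta)


def clamp_op(x, lo, hi):
    xv = _val(x)
    out = np.clip(xv, lo, hi)
    if not isinstance(x, Tensor):
        return out
    mask = (xv > lo) & (xv < hi)
    return Tensor(out, [(x, lambda g: g * mask)])


def ball_project_op(x, center, delta):
    """Projection onto the Euclidean ball ``B(center, delta)``.

    For 2-d input each column is projected independently (batch mode).
    Only ``x`` is differentiable; ``center``/``delta`` are data.
    """
    xv = _val(x)
    center = np.asarray(center, dtype=float)
    diff = xv - center
    r = np.linalg.norm(diff, axis=0) if xv.ndim == 2 else np.linalg.norm(diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(r > delta, np.where(r > 0, delta / np.where(r > 0, r, 1.0), 1.0), 1.0)
    out = center + s * diff
    if not isinstance(x, Tensor):
        return out

    def vjp(g):
        if xv.ndim == 2:
            rr = np.where(r > 0, r, 1.0)
            q = diff / rr
            inner = np.sum(q * g, axis=0)
            return np.where(r > delta, s * (g - q * inner), g)
        if r > delta:
            q = diff / r
            return s * (g - q * np.dot(q, g))
        return g

    return Tensor(out, [(x, vjp)])


def mse(x, target):
    """Mean squared error over all entries; returns a scalar node."""
    xv, tv = _val(x), _val(target)
    diff = xv - tv
    out = float(np.mean(diff * diff))
    if not isinstance(x, Tensor):
        return out
    n = diff.size

    def vjp(g):
        return (2.0 / n) * g * diff

    return Tensor(out, [(x, vjp)])


def _toposort(root):
    order, visited = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if id(parent) not in visited:
                stack.append((parent, False))
    return order


def backward(root, seed=None):
    """Accumulate gradients of ``root`` into every reachable leaf.

    ``seed`` is the cotangent at the root (defaults to ones, i.e. the gradient
    of ``sum(root)``; for a scalar loss this is the ordinary gradient).
    """
    if not isinstance(root, Tensor):
        raise TypeError("backward expects a Tensor root")
    grads = {id(root): np.ones_like(root.value) if seed is None else np.asarray(seed, dtype=float)}
    for node in reversed(_toposort(root)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node.requires_grad:
            node.grad = g if node.grad is None else node.grad + g
        for parent, vjp in node.parents:
            pg = vjp(g)
            if id(parent) in grads:
                grads[id(parent)] = grads[id(parent)] + pg
            else:
                grads[id(parent)] = pg


def graph_size(root):
    """Number of Tensor nodes reachable from ``root`` — the derivative-graph
    footprint of a traced computation."""
    return len(_toposort(root))
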
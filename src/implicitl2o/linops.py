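"""Linear operators with verified adjoints.

Every solver in the package talks to measurement physics through a
:class:`LinearMap`: a pair of callables (forward, adjoint) plus an operator
norm bound used to set stable step sizes.  Concrete maps provided here are
dense/sparse matrix products and the parallel-beam Radon system used by the
sparse-angle CT experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "LinearMap",
    "MatrixMap",
    "IdentityMap",
    "RadonGeometry",
    "make_matrix_map",
    "build_radon_map",
    "estimate_norm",
    "save_sparse_map",
    "load_sparse_map",
]

#: safety factor applied on top of power-iteration norm estimates so that
#: step-size conditions derived from ``norm_bound`` hold strictly
NORM_SAFETY = 1.01


class LinearMap:
    """A linear operator ``R^in_dim -> R^out_dim`` with an adjoint.

    ``forward`` and ``adjoint`` accept 1-d vectors or 2-d column-stacked
    batches.  ``norm_bound`` is an upper bound on the spectral norm.
    """

    def __init__(self, in_dim, out_dim, forward, adjoint, norm_bound=None):
        if in_dim < 1 or out_dim < 1:
            raise ValueError("LinearMap dimensions must be positive")
        self.in_dim = int(in_dim)
        self.out_dim = int(out_dim)
        self._forward = forward
        self._adjoint = adjoint
        self.norm_bound = norm_bound

    def forward(self, x):
        return self._forward(np.asarray(x, dtype=float))

    def adjoint(self, y):
        return self._adjoint(np.asarray(y, dtype=float))

    __call__ = forward

    def __repr__(self):  # pragma: no cover
        return f"{type(self).__name__}({self.out_dim}x{self.in_dim}, norm_bound={self.norm_bound})"


class MatrixMap(LinearMap):
    """LinearMap backed by an explicit dense or scipy.sparse matrix."""

    def __init__(self, A, norm_bound=None):
        if sp.issparse(A):
            self.A = A.tocsr()
            finite = np.all(np.isfinite(self.A.data))
        else:
            self.A = np.asarray(A, dtype=float)
            if self.A.ndim != 2:
                raise ValueError("matrix must be 2-d")
            finite = np.all(np.isfinite(self.A))
        if not finite:
            raise ValueError("matrix contains non-finite entries")
        out_dim, in_dim = self.A.shape
        super().__init__(
            in_dim,
            out_dim,
            lambda x: self.A @ x,
            lambda y: self.A.T @ y,
            norm_bound=norm_bound,
        )
        if self.norm_bound is None:
            self.norm_bound = NORM_SAFETY * estimate_norm(self, iters=60, seed=0)

    def dense(self):
        return self.A.toarray() if sp.issparse(self.A) else self.A


class IdentityMap(LinearMap):
    def __init__(self, dim):
        super().__init__(dim, dim, lambda x: x, lambda y: y, norm_bound=1.0)


def make_matrix_map(A):
    """Wrap an explicit matrix as a :class:`LinearMap` (adjoint = transpose)."""
    return MatrixMap(A)


@dataclass(frozen=True)
class RadonGeometry:
    """Parallel-beam acquisition geometry.

    ``n_angles`` view angles equally spaced on [0, pi); ``n_beams`` parallel
    rays per angle with offsets equally spaced across the image diagonal.
    The image is ``image_side`` x ``image_side`` with unit pixels centered at
    half-integer offsets, the whole image centered at the origin.
    """

    image_side: int
    n_angles: int
    n_beams: int

    def __post_init__(self):
        if self.image_side < 1 or self.n_angles < 1 or self.n_beams < 1:
            raise ValueError("RadonGeometry dimensions must be >= 1")

    @property
    def n_rays(self):
        return self.n_angles * self.n_beams

    @property
    def n_pixels(self):
        return self.image_side ** 2


def _ray_trace(side, cos_a, sin_a, offset):
    """Exact pixel-intersection lengths of one ray through the pixel grid.

    The ray is ``t*(-sin a, cos a) + s*(cos a, sin a)`` for s in R.  Crossing
    parameters with all grid lines are merged; each inter-crossing segment
    lies in exactly one pixel (grid lines include the image boundary), so its
    length is that pixel's weight (Siddon's method).
    """
    half = side / 2.0
    ox, oy = -offset * sin_a, offset * cos_a
    lines = np.arange(side + 1, dtype=float) - half
    params = []
    if abs(cos_a) > 1e-12:
        params.append((lines - ox) / cos_a)
    if abs(sin_a) > 1e-12:
        params.append((lines - oy) / sin_a)
    if not params:  # degenerate direction cannot occur for unit directions
        return np.empty(0, dtype=np.int64), np.empty(0)
    ts = np.unique(np.concatenate(params))
    if ts.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0)
    lengths = np.diff(ts)
    mids = 0.5 * (ts[:-1] + ts[1:])
    px = ox + mids * cos_a
    py = oy + mids * sin_a
    inside = (np.abs(px) < half) & (np.abs(py) < half) & (lengths > 1e-14)
    cols = np.floor(px[inside] + half).astype(np.int64)
    rows = np.floor(py[inside] + half).astype(np.int64)
    flat = rows * side + cols
    return flat, lengths[inside]


def build_radon_map(geom: RadonGeometry):
    """Explicit sparse parallel-beam Radon system matrix.

    Rows are ordered angle-major: row ``a * n_beams + b`` is the line integral
    for angle ``a``, beam ``b``.  The adjoint (transpose) is unfiltered
    backprojection.  Deterministic for a fixed geometry.
    """
    side = geom.image_side
    angles = np.arange(geom.n_angles) * np.pi / geom.n_angles
    diag = side * np.sqrt(2.0)
    if geom.n_beams > 1:
        offsets = np.linspace(-diag / 2.0, diag / 2.0, geom.n_beams)
    else:
        offsets = np.array([0.0])

    data, row_idx, col_idx = [], [], []
    for a, ang in enumerate(angles):
        ca, sa = np.cos(ang), np.sin(ang)
        for b, t in enumerate(offsets):
            flat, w = _ray_trace(side, ca, sa, t)
            if flat.size:
                row = a * geom.n_beams + b
                row_idx.append(np.full(flat.size, row, dtype=np.int64))
                col_idx.append(flat)
                data.append(w)
    if data:
        A = sp.csr_matrix(
            (np.concatenate(data), (np.concatenate(row_idx), np.concatenate(col_idx))),
            shape=(geom.n_rays, geom.n_pixels),
        )
    else:  # pragma: no cover - all rays miss the image
        A = sp.csr_matrix((geom.n_rays, geom.n_pixels))
    m = MatrixMap(A)
    m.geometry = geom
    return m


def estimate_norm(map: LinearMap, iters: int = 50, seed: int = 0):
    """Power-iteration estimate of the operator (spectral) norm.

    Runs on ``adjoint o forward``; the Rayleigh-quotient estimate is
    nondecreasing in ``iters`` for a fixed seed.  The estimate times
    ``NORM_SAFETY`` is stored into ``map.norm_bound``.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(map.in_dim)
    v /= np.linalg.norm(v)
    est = 0.0
    for _ in range(iters):
        w = map.adjoint(map.forward(v))
        nw = np.linalg.norm(w)
        if nw == 0.0:
            return 0.0
        est = np.sqrt(nw)  # ||A^T A v|| -> sigma_max^2 for unit v
        v = w / nw
    map.norm_bound = NORM_SAFETY * float(est)
    return float(est)


def save_sparse_map(map: MatrixMap, path):
    """Write a sparse matrix map as plain-text triplets with a JSON header."""
    A = map.A if sp.issparse(map.A) else sp.csr_matrix(map.A)
    coo = A.tocoo()
    header = {"shape": list(A.shape), "nnz": int(coo.nnz)}
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r} {c} {float(v)!r}\n")


def load_sparse_map(path):
    with open(path) as fh:
        header = json.loads(fh.readline())
        rows, cols, vals = [], [], []
        for line in fh:
            r, c, v = line.split()
            rows.append(int(r))
            cols.append(int(c))
            vals.append(float(v))
    A = sp.csr_matrix((vals, (rows, cols)), shape=tuple(header["shape"]))
    return MatrixMap(A)
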
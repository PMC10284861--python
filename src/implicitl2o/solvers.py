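"""Fixed-point iteration and linearized ADMM.

An implicit model's inference is the limit of ``x^{k+1} = T(x^k; d)`` for an
averaged operator ``T``.  This module supplies the generic driver
(:func:`iterate_to_fixed_point`), the proximal-gradient operator for sparse
recovery, and linearized ADMM (L-ADMM) for constrained composite problems

    min  f(Kx) + h(x)   s.t.  ||Mx - d|| <= delta,

whose iteration updates the tuple ``(p, w, nu1, nu2, x)`` with the primal
``x`` updated last.

All routines accept vectors or column-stacked batches: every update is
columnwise, so a batch of independent problems (sharing K, M and step sizes)
iterates in lockstep at matrix-multiply speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

from .linops import LinearMap
from .prox_ops import project_ball

__all__ = [
    "DivergenceError",
    "FixedPointState",
    "LadmmState",
    "LadmmProblem",
    "iterate_to_fixed_point",
    "make_pg_operator",
    "make_ladmm_problem",
    "ladmm_step",
    "ladmm_solve",
]

#: absolute slack allowed on ||Mx - d|| <= delta at the returned limit
FEASIBILITY_TOL = 1e-6


class DivergenceError(RuntimeError):
    """Raised when an iterate turns non-finite; carries the iteration index."""

    def __init__(self, k, where="iterate"):
        super().__init__(f"non-finite {where} at iteration {k}")
        self.k = k
        self.where = where


@dataclass
class FixedPointState:
    """Terminal state of a fixed-point run.

    ``residual`` is ``||x^k - x^{k-1}||`` at the stopping iterate and
    ``history`` collects it for every step taken (length == k).
    """

    x: np.ndarray
    k: int
    residual: float
    history: List[float] = field(default_factory=list)
    converged: bool = True
    aux: Optional["LadmmState"] = None
    feasibility: Optional[float] = None


def _norm(v):
    return float(np.linalg.norm(v))


def iterate_to_fixed_point(T: Callable, x0, tol: float, max_iter: int) -> FixedPointState:
    """Iterate ``x <- T(x)`` until ``||x^k - x^{k-1}|| <= tol*(1 + ||x^k||)``
    or ``max_iter`` steps; deterministic given ``T`` and ``x0``."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    x = np.asarray(x0, dtype=float)
    history: List[float] = []
    residual = np.inf
    converged = False
    for k in range(1, max_iter + 1):
        x_next = T(x)
        if not np.all(np.isfinite(x_next)):
            raise DivergenceError(k)
        residual = _norm(x_next - x)
        if not np.isfinite(residual):  # finite iterate, overflowing step
            raise DivergenceError(k)
        history.append(residual)
        x = x_next
        if residual <= tol * (1.0 + _norm(x)):
            converged = True
            break
    return FixedPointState(x=x, k=len(history), residual=residual,
                           history=history, converged=converged)


def make_pg_operator(W: LinearMap, A: LinearMap, d, theta):
    """Proximal-gradient model operator ``x -> shrink(x - W(Ax - d), theta)``.

    With ``W = c A^T`` (c below 1/||A||^2) and threshold ``c*tau`` this is the
    classical ISTA update for the lasso; leaving ``W`` and ``theta`` tunable
    turns it into a learned sparse-recovery model.
    """
    from .prox_ops import shrink

    if W.in_dim != A.out_dim or W.out_dim != A.in_dim:
        raise ValueError(
            f"shape mismatch: W is {W.out_dim}x{W.in_dim}, A is {A.out_dim}x{A.in_dim}"
        )
    d = np.asarray(d, dtype=float)

    def T(x):
        return shrink(x - W.forward(A.forward(x) - d), theta)

    return T


@dataclass
class LadmmState:
    """The L-ADMM variable tuple ``(p, w, nu1, nu2, x)``.

    ``p, nu1`` live in the range of K; ``w, nu2`` in the range of M;
    ``x`` is the primal.  Entries may be column-stacked batches.
    """

    p: np.ndarray
    w: np.ndarray
    nu1: np.ndarray
    nu2: np.ndarray
    x: np.ndarray

    def copy(self):
        return LadmmState(*(np.array(v) for v in
                            (self.p, self.w, self.nu1, self.nu2, self.x)))

    def pack(self):
        return np.concatenate([self.p, self.w, self.nu1, self.nu2, self.x], axis=0)

    @staticmethod
    def unpack(vec, k_dim, m_dim, n_dim):
        i = np.cumsum([k_dim, m_dim, k_dim, m_dim])
        return LadmmState(vec[: i[0]], vec[i[0]:i[1]], vec[i[1]:i[2]],
                          vec[i[2]:i[3]], vec[i[3]:])


@dataclass
class LadmmProblem:
    """Data, operators, proxes and step sizes for one L-ADMM instance.

    Default step sizes satisfy ``alpha*beta*(||K||^2 + ||M||^2) = 0.9`` with
    ``alpha = lam = 2*beta`` (see :func:`make_ladmm_problem`), which kept the
    composite iteration convergent on every instance we tested while leaving
    a strict stability margin.
    """

    K: LinearMap
    M: LinearMap
    d: np.ndarray
    delta: float
    prox_f: Callable   # (v, lam) -> v
    prox_h: Callable   # (v, beta) -> v
    alpha: float
    beta: float
    lam: float


def make_ladmm_problem(K, M, d, delta, prox_f, prox_h=None,
                       alpha=None, beta=None, lam=None):
    """Assemble an :class:`LadmmProblem`, filling step sizes by the default
    stability rule when not given explicitly."""
    if prox_h is None:
        prox_h = lambda v, t: v  # h == 0
    d = np.asarray(d, dtype=float)
    if np.any(np.asarray(delta) < 0):
        raise ValueError("delta must be nonnegative")
    # stability: alpha*beta*(||K||^2 + ||M||^2) <= 1 with a 0.9 safety
    # factor; the dual steps run at twice the primal step (alpha = lam = 2*beta)
    Lb = K.norm_bound ** 2 + M.norm_bound ** 2
    if beta is None:
        beta = np.sqrt(0.45 / Lb)
    if lam is None:
        lam = 2.0 * beta
    if alpha is None:
        alpha = lam
    if min(alpha, beta, lam) <= 0:
        raise ValueError("step sizes must be positive")
    return LadmmProblem(K=K, M=M, d=d, delta=delta, prox_f=prox_f,
                        prox_h=prox_h, alpha=alpha, beta=beta, lam=lam)


def ladmm_step(state: LadmmState, prob: LadmmProblem) -> LadmmState:
    """One L-ADMM sweep; the six updates in order (p, w, nu1, nu2, r, x) with
    the primal ``x`` updated last.  Side-effect-free on its input."""
    K, M = prob.K, prob.M
    al, lam, be = prob.alpha, prob.lam, prob.beta
    Kx = K.forward(state.x)
    Mx = M.forward(state.x)

    p = prob.prox_f(state.p + lam * (state.nu1 + al * (Kx - state.p)), lam)
    _check(p, "p-update")
    w = project_ball(state.w + lam * (state.nu2 + al * (Mx - state.w)),
                     prob.d, prob.delta)
    _check(w, "w-update")
    nu1 = state.nu1 + al * (Kx - p)
    _check(nu1, "nu1-update")
    nu2 = state.nu2 + al * (Mx - w)
    _check(nu2, "nu2-update")
    r = K.adjoint(2.0 * nu1 - state.nu1) + M.adjoint(2.0 * nu2 - state.nu2)
    _check(r, "r-update")
    x = prob.prox_h(state.x - be * r, be)
    _check(x, "x-update")
    return LadmmState(p=p, w=w, nu1=nu1, nu2=nu2, x=x)


def _check(v, where):
    if not np.all(np.isfinite(v)):
        raise DivergenceError(-1, where)


def initial_ladmm_state(prob: LadmmProblem, x0) -> LadmmState:
    """Consistency start: p = K x0, w = M x0, duals zero."""
    x0 = np.asarray(x0, dtype=float)
    return LadmmState(p=prob.K.forward(x0), w=prob.M.forward(x0),
                      nu1=np.zeros_like(prob.K.forward(x0)),
                      nu2=np.zeros_like(prob.M.forward(x0)), x=x0)


def ladmm_solve(prob: LadmmProblem, x0, tol: float, max_iter: int) -> FixedPointState:
    """Run L-ADMM to a fixed point of the full variable tuple.

    The stopping residual is the norm of the change of the packed
    ``(p, w, nu1, nu2, x)`` tuple, relative form ``residual/(1 + ||state||)``
    — using the full tuple avoids premature stops when only ``x`` stalls.
    Hitting ``max_iter`` flags the state unconverged rather than raising.
    """
    state0 = initial_ladmm_state(prob, x0)
    k_dim, m_dim = prob.K.out_dim, prob.M.out_dim
    n_dim = prob.K.in_dim

    def T(vec):
        st = LadmmState.unpack(vec, k_dim, m_dim, n_dim)
        try:
            return ladmm_step(st, prob).pack()
        except DivergenceError:
            raise

    fps = iterate_to_fixed_point(T, state0.pack(), tol, max_iter)
    final = LadmmState.unpack(fps.x, k_dim, m_dim, n_dim)
    diff = prob.M.forward(final.x) - prob.d  # batched runs need batched d
    feas = np.linalg.norm(diff, axis=0) if diff.ndim == 2 else float(np.linalg.norm(diff))
    return FixedPointState(x=final.x, k=fps.k, residual=fps.residual,
                           history=fps.history, converged=fps.converged,
                           aux=final, feasibility=feas)


def write_trace(state: FixedPointState, path):
    """Dump a solver residual history as CSV (columns: k, residual)."""
    with open(path, "w") as fh:
        fh.write("k,residual\n")
        for k, res in enumerate(state.history, start=1):
            fh.write(f"{k},{res!r}\n")
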
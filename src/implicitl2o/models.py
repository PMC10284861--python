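"""Implicit models: inference as the fixed point of a tunable iteration.

Three concrete models share one shape — an inference is the limit of an
averaged iteration map built from the model weights:

* sparse recovery: ``x -> shrink(x - W(Ax - d), theta)``, a learned
  proximal-gradient (ISTA-like) operator with weights ``(W, theta, tau)``;
* implicit dictionary model (IDM): ``argmin ||Kx||_1 s.t. Ax = d`` with a
  learned square sparsifying transform ``K``, solved by linearized ADMM;
* CT reconstruction: ``argmin_{x in [0,1]^n} f_Omega(Kx) s.t. ||Ax-d|| <= delta``
  with a learned proximal for the regularizer ``f_Omega``, solved by L-ADMM
  whose final update is the box projection — so pixel bounds hold bit-exactly.

Each model is exposed twice: as a plain function (``*_infer``) returning the
inference together with its solver state, and as a scikit-learn style
estimator with ``fit``/``predict`` whose ``fit`` runs Jacobian-free
backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from . import autodiff as ad
from .linops import IdentityMap, LinearMap, MatrixMap, make_matrix_map
from .prox_ops import LearnedProx, project_box, prox_l1
from .solvers import (FixedPointState, iterate_to_fixed_point, ladmm_solve,
                      make_ladmm_problem, make_pg_operator)
from .training import TrainConfig, train

__all__ = [
    "SparseRecoveryWeights",
    "IdmWeights",
    "CtWeights",
    "sparse_recovery_infer",
    "idm_infer",
    "ct_infer",
    "backprojection_baseline",
    "SparseRecoveryModel",
    "ImplicitDictionaryModel",
    "CTReconstructor",
]

#: relative safety margin on the fidelity ball: the solver enforces radius
#: delta*(1 - margin) so the advertised tolerance delta holds exactly at
#: finite iteration counts
CT_BALL_MARGIN = 0.02


# ---------------------------------------------------------------------------
# weight containers
# ---------------------------------------------------------------------------

@dataclass
class SparseRecoveryWeights:
    W: LinearMap            # n <- m, tunable
    theta: float            # shrink threshold (>= 0)
    tau: float = 1.0        # sparsity weight, absorbed into theta in practice

    def __post_init__(self):
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")


@dataclass
class IdmWeights:
    K: LinearMap            # square sparsifying transform

    def __post_init__(self):
        if self.K.in_dim != self.K.out_dim:
            raise ValueError("IDM transform K must be square")


@dataclass
class CtWeights:
    Omega: LearnedProx
    K: LinearMap
    alpha: Optional[float] = None   # L-ADMM step sizes; None -> stability rule
    beta: Optional[float] = None
    lam: Optional[float] = None
    delta: float = 0.0              # fidelity-ball radius (noise tolerance)

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")


# ---------------------------------------------------------------------------
# functional inference
# ---------------------------------------------------------------------------

def sparse_recovery_infer(weights: SparseRecoveryWeights, A: LinearMap, d,
                          tol=1e-8, max_iter=2000):
    """Fixed point of the learned proximal-gradient operator."""
    T = make_pg_operator(weights.W, A, d, weights.theta)
    d = np.asarray(d, dtype=float)
    x0 = np.zeros(A.in_dim) if d.ndim == 1 else np.zeros((A.in_dim, d.shape[1]))
    state = iterate_to_fixed_point(T, x0, tol, max_iter)
    return state.x, state


def idm_infer(weights: IdmWeights, A: LinearMap, d, tol=1e-9, max_iter=4000,
              delta=0.0):
    """Solve ``argmin ||Kx||_1 s.t. Ax = d`` (equality via a zero-radius
    fidelity ball) by L-ADMM, starting from zero."""
    prob = make_ladmm_problem(weights.K, A, d, delta,
                              prox_f=lambda v, lam: prox_l1(v, lam))
    d = np.asarray(d, dtype=float)
    x0 = np.zeros(A.in_dim) if d.ndim == 1 else np.zeros((A.in_dim, d.shape[1]))
    state = ladmm_solve(prob, x0, tol, max_iter)
    return state.x, state


def backprojection_baseline(A: LinearMap, d):
    """Unfiltered backprojection ``A^T d`` with a least-squares intensity
    scale (fit in measurement space), clamped to [0,1]."""
    d = np.asarray(d, dtype=float)
    bp = A.adjoint(d)
    abp = A.forward(bp)
    denom = np.sum(abp * abp, axis=0) if d.ndim == 2 else float(np.dot(abp, abp))
    num = np.sum(abp * d, axis=0) if d.ndim == 2 else float(np.dot(abp, d))
    scale = np.where(np.asarray(denom) > 0, num / np.where(np.asarray(denom) > 0, denom, 1.0), 0.0)
    return project_box(scale * bp, 0.0, 1.0)


def ct_infer(weights: CtWeights, A: LinearMap, d, tol=1e-7, max_iter=3000,
             margin=CT_BALL_MARGIN):
    """Constrained CT reconstruction by L-ADMM.

    The solver enforces the fidelity ball with radius ``delta*(1-margin)``;
    the *advertised* constraint ``||Ax-d|| <= delta`` therefore holds exactly
    once the solve converges, and the final box projection guarantees
    ``x in [0,1]^n`` bit-exactly regardless of convergence.
    """
    prob = make_ladmm_problem(
        weights.K, A, np.asarray(d, dtype=float),
        np.maximum(weights.delta * (1.0 - margin), 0.0),
        prox_f=lambda v, lam: weights.Omega.apply(v),
        prox_h=lambda v, beta: project_box(v, 0.0, 1.0),
        alpha=weights.alpha, beta=weights.beta, lam=weights.lam,
    )
    x0 = backprojection_baseline(A, d)
    state = ladmm_solve(prob, x0, tol, max_iter)
    return state.x, state


# ---------------------------------------------------------------------------
# estimator cores (the JFB training protocol)
# ---------------------------------------------------------------------------

class _SparseRecoveryCore:
    def __init__(self, A: LinearMap, W: np.ndarray, theta: float):
        self.A = A
        self.W = np.array(W, dtype=float)
        self.theta = np.asarray(float(theta))

    def param_arrays(self):
        return {"W": self.W, "theta": self.theta}

    def apply_param_arrays(self, arrays):
        self.W = np.asarray(arrays["W"], dtype=float)
        self.theta = np.asarray(float(arrays["theta"]))

    def project_params(self):
        self.theta = np.asarray(max(float(self.theta), 0.0))

    def solve(self, d, tol, max_iter):
        w = SparseRecoveryWeights(make_matrix_map(self.W), float(self.theta))
        _, state = sparse_recovery_infer(w, self.A, d, tol, max_iter)
        return state

    def output_of(self, state):
        return state.x

    def traced_step(self, params, state, d):
        x = state.x
        resid = self.A.forward(x) - np.asarray(d, dtype=float)   # constant
        corr = ad.matvec(params["W"], resid)
        return ad.shrink_op(ad.sub(x, corr), params["theta"])


class _IdmCore:
    def __init__(self, A: LinearMap, K: np.ndarray, delta=0.0):
        self.A = A
        self.K = np.array(K, dtype=float)
        self.delta = float(delta)
        self._prob = None

    def param_arrays(self):
        return {"K": self.K}

    def apply_param_arrays(self, arrays):
        self.K = np.asarray(arrays["K"], dtype=float)

    def project_params(self):
        pass

    def solve(self, d, tol, max_iter):
        self._prob = make_ladmm_problem(make_matrix_map(self.K), self.A,
                                        np.asarray(d, dtype=float), self.delta,
                                        prox_f=lambda v, lam: prox_l1(v, lam))
        d = np.asarray(d, dtype=float)
        x0 = np.zeros(self.A.in_dim) if d.ndim == 1 else \
            np.zeros((self.A.in_dim, d.shape[1]))
        return ladmm_solve(self._prob, x0, tol, max_iter)

    def output_of(self, state):
        return state.x

    def traced_step(self, params, state, d):
        """One L-ADMM sweep traced in K only (data terms are constants)."""
        st = state.aux
        prob = self._prob
        al, lam, be = prob.alpha, prob.lam, prob.beta
        Kt = params["K"]
        Kx = ad.matvec(Kt, st.x)
        p_arg = ad.add(st.p, ad.scale(ad.add(ad.scale(ad.sub(Kx, st.p), al),
                                             st.nu1), lam))
        p_new = ad.shrink_op(p_arg, lam)
        # w and nu2 updates involve only M and constants
        from .prox_ops import project_ball
        Mx = prob.M.forward(st.x)
        w_new = project_ball(st.w + lam * (st.nu2 + al * (Mx - st.w)),
                             prob.d, prob.delta)
        nu1_new = ad.add(ad.scale(ad.sub(Kx, p_new), al), st.nu1)
        nu2_new = st.nu2 + al * (Mx - w_new)
        r = ad.add(ad.matvec_t(Kt, ad.sub(ad.scale(nu1_new, 2.0), st.nu1)),
                   prob.M.adjoint(2.0 * nu2_new - st.nu2))
        return ad.sub(st.x, ad.scale(r, be))   # prox_h is the identity


class _CtCore:
    def __init__(self, A: LinearMap, omega: LearnedProx, delta, margin=CT_BALL_MARGIN):
        self.A = A
        self.omega = omega
        self.delta = delta           # scalar, per-column array, or callable d->delta
        self.margin = float(margin)
        self._prob = None

    def _delta_of(self, d):
        return self.delta(d) if callable(self.delta) else self.delta

    def param_arrays(self):
        return dict(self.omega.weights)

    def apply_param_arrays(self, arrays):
        for k in self.omega.weights:
            self.omega.weights[k] = np.asarray(arrays[k], dtype=float)

    def project_params(self):
        self.omega.normalize()

    def solve(self, d, tol, max_iter):
        d = np.asarray(d, dtype=float)
        delta = self._delta_of(d)
        self._prob = make_ladmm_problem(
            IdentityMap(self.A.in_dim), self.A, d,
            np.maximum(np.asarray(delta) * (1.0 - self.margin), 0.0),
            prox_f=lambda v, lam: self.omega.apply(v),
            prox_h=lambda v, beta: project_box(v, 0.0, 1.0),
        )
        x0 = backprojection_baseline(self.A, d)
        return ladmm_solve(self._prob, x0, tol, max_iter)

    def output_of(self, state):
        return state.x

    def traced_step(self, params, state, d):
        """One L-ADMM sweep traced through the learned proximal (K = I)."""
        st = state.aux
        prob = self._prob
        al, lam, be = prob.alpha, prob.lam, prob.beta
        p_arg = st.p + lam * (st.nu1 + al * (st.x - st.p))       # constant
        p_new = self.omega.apply_traced(p_arg, params)
        from .prox_ops import project_ball
        Mx = prob.M.forward(st.x)
        w_new = project_ball(st.w + lam * (st.nu2 + al * (Mx - st.w)),
                             prob.d, prob.delta)
        nu1_new = ad.add(ad.scale(ad.sub(st.x, p_new), al), st.nu1)
        nu2_new = st.nu2 + al * (Mx - w_new)
        r = ad.add(ad.sub(ad.scale(nu1_new, 2.0), st.nu1),
                   prob.M.adjoint(2.0 * nu2_new - st.nu2))
        return ad.clamp_op(ad.sub(st.x, ad.scale(r, be)), 0.0, 1.0)


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------

def _columns(Z):
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("expected a 2-d array of shape (n_samples, dim)")
    return Z.T


class _ImplicitEstimator(BaseEstimator):
    """Shared fit/predict plumbing; subclasses build their core."""

    def fit(self, D, X):
        Dc, Xc = _columns(D), _columns(X)
        if Dc.shape[1] != Xc.shape[1]:
            raise ValueError("D and X must have the same number of samples")
        self.core_ = self._make_core(Dc, Xc)
        cfg = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                          lr=self.lr, fp_tol=self.fp_tol,
                          fp_max_iter=self.fp_max_iter, seed=self.seed)
        _, self.loss_history_ = train(self.core_, (Dc, Xc), cfg)
        self._finalize()
        return self

    def predict(self, D):
        if not hasattr(self, "core_"):
            raise RuntimeError("estimator is not fitted")
        state = self.core_.solve(_columns(D), self.tol, self.max_iter)
        return self.core_.output_of(state).T

    def predict_with_state(self, D):
        state = self.core_.solve(_columns(D), self.tol, self.max_iter)
        return self.core_.output_of(state).T, state

    def _finalize(self):
        pass


class SparseRecoveryModel(_ImplicitEstimator):
    """Learned ISTA-style sparse recovery with weights ``(W, theta)``.

    ``W`` is initialized at ``c A^T`` and ``theta`` at ``c * tau`` with
    ``c = 1/norm_bound(A)^2``, i.e. the classical ISTA operator for the lasso
    with weight ``tau``; training then tunes both.
    """

    def __init__(self, A=None, tau=0.1, tol=1e-8, max_iter=2000,
                 epochs=20, batch_size=32, lr=1e-3,
                 fp_tol=1e-6, fp_max_iter=100, seed=0):
        self.A = A
        self.tau = tau
        self.tol = tol
        self.max_iter = max_iter
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.fp_tol = fp_tol
        self.fp_max_iter = fp_max_iter
        self.seed = seed

    def _make_core(self, Dc, Xc):
        A_map = self.A if isinstance(self.A, LinearMap) else make_matrix_map(self.A)
        self.A_map_ = A_map
        c = 1.0 / A_map.norm_bound ** 2
        W0 = c * (A_map.A.T if isinstance(A_map, MatrixMap)
                  else np.column_stack([A_map.adjoint(e) for e in np.eye(A_map.out_dim)]))
        return _SparseRecoveryCore(A_map, W0, c * self.tau)

    def _finalize(self):
        self.W_ = self.core_.W
        self.theta_ = float(self.core_.theta)

    def infer(self, d):
        w = SparseRecoveryWeights(make_matrix_map(self.core_.W), self.theta_, self.tau)
        return sparse_recovery_infer(w, self.A_map_, d, self.tol, self.max_iter)


class ImplicitDictionaryModel(_ImplicitEstimator):
    """IDM: basis pursuit through a learned square sparsifying transform.

    ``K`` starts at identity plus small seeded Gaussian noise; training moves
    it toward a transform under which true signals have sparse codes ``Kx``.
    """

    def __init__(self, A=None, init_scale=0.01, delta=0.0,
                 tol=1e-10, max_iter=20000, epochs=150, batch_size=50, lr=1e-2,
                 fp_tol=1e-8, fp_max_iter=800, seed=0):
        self.A = A
        self.init_scale = init_scale
        self.delta = delta
        self.tol = tol
        self.max_iter = max_iter
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.fp_tol = fp_tol
        self.fp_max_iter = fp_max_iter
        self.seed = seed

    def _make_core(self, Dc, Xc):
        A_map = self.A if isinstance(self.A, LinearMap) else make_matrix_map(self.A)
        self.A_map_ = A_map
        n = A_map.in_dim
        rng = np.random.default_rng(self.seed)
        K0 = np.eye(n) + self.init_scale * rng.standard_normal((n, n))
        return _IdmCore(A_map, K0, self.delta)

    def _finalize(self):
        self.K_ = self.core_.K

    def infer(self, d):
        return idm_infer(IdmWeights(make_matrix_map(self.K_)), self.A_map_, d,
                         self.tol, self.max_iter, self.delta)

    def sparse_code(self, X):
        """The learned code ``Kx`` for row-stacked signals."""
        return (self.K_ @ _columns(X)).T


class CTReconstructor(_ImplicitEstimator):
    """Constrained CT reconstruction with a learned proximal regularizer.

    ``delta`` defaults to ``noise_frac * ||d||`` per sinogram (discrepancy
    principle at the configured noise level).
    """

    def __init__(self, A=None, noise_frac=0.015, delta=None, hidden=32,
                 margin=CT_BALL_MARGIN, tol=1e-7, max_iter=3000,
                 epochs=5, batch_size=10, lr=1e-3,
                 fp_tol=1e-5, fp_max_iter=400, seed=0):
        self.A = A
        self.noise_frac = noise_frac
        self.delta = delta
        self.hidden = hidden
        self.margin = margin
        self.tol = tol
        self.max_iter = max_iter
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.fp_tol = fp_tol
        self.fp_max_iter = fp_max_iter
        self.seed = seed

    def _delta_for(self, Dc):
        if self.delta is not None:
            return self.delta
        norms = np.linalg.norm(Dc, axis=0) if Dc.ndim == 2 else float(np.linalg.norm(Dc))
        return self.noise_frac * norms

    def _make_core(self, Dc, Xc):
        A_map = self.A if isinstance(self.A, LinearMap) else make_matrix_map(self.A)
        self.A_map_ = A_map
        omega = LearnedProx(A_map.in_dim, hidden=self.hidden, seed=self.seed)
        # delta is data-dependent (per sinogram), so the core carries the rule
        return _CtCore(A_map, omega, self._delta_for, margin=self.margin)

    def initialize(self):
        """Build the (untrained) model: the learned proximal starts as the
        exact averaged-identity prox, so the model is usable before fit."""
        self.core_ = self._make_core(None, None)
        self.loss_history_ = []
        self._finalize()
        return self

    def _finalize(self):
        self.prox_ = self.core_.omega

    def infer(self, d):
        d = np.asarray(d, dtype=float)
        w = CtWeights(Omega=self.core_.omega, K=IdentityMap(self.A_map_.in_dim),
                      delta=float(np.asarray(self._delta_for(d))))
        return ct_infer(w, self.A_map_, d, self.tol, self.max_iter, self.margin)
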
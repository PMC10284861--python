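"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy.optimize import linprog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def basis_pursuit_oracle(A, d):
    """Reference minimizer of ||x||_1 s.t. Ax = d via the standard LP split
    x = x+ - x- solved by an interior-point/simplex method (HiGHS)."""
    m, n = A.shape
    res = linprog(np.ones(2 * n), A_eq=np.hstack([A, -A]), b_eq=d,
                  bounds=[(0, None)] * (2 * n), method="highs")
    assert res.success, res.message
    return res.x[:n] - res.x[n:]


def ista_reference(A, d, step, tau, n_iter, x0=None):
    """Hand-rolled ISTA for 0.5*||Ax-d||^2-free lasso form used by the model:
    x <- soft(x - step*A^T(Ax-d), step*tau); returns the iterate history."""
    x = np.zeros(A.shape[1]) if x0 is None else x0.copy()
    out = []
    for _ in range(n_iter):
        u = x - step * (A.T @ (A @ x - d))
        x = np.sign(u) * np.maximum(np.abs(u) - step * tau, 0.0)
        out.append(x.copy())
    return out


@pytest.fixture
def bp_oracle():
    return basis_pursuit_oracle


@pytest.fixture
def ista_oracle():
    return ista_reference
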
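"""Fixed-point driver, proximal-gradient operator and L-ADMM."""

import numpy as np
import pytest

from implicitl2o.linops import make_matrix_map
from implicitl2o.prox_ops import prox_l1, shrink
from implicitl2o.solvers import (DivergenceError, LadmmState,
                                 initial_ladmm_state, iterate_to_fixed_point,
                                 ladmm_solve, ladmm_step, make_ladmm_problem,
                                 make_pg_operator)


class TestIterateToFixedPoint:
    def test_geometric_contraction(self):
        st = iterate_to_fixed_point(lambda x: x / 2, np.array([1.0]), 1e-6, 100)
        assert st.converged
        assert abs(st.x[0]) < 1e-5
        ratios = np.diff(np.log(st.history))
        np.testing.assert_allclose(np.exp(ratios), 0.5, atol=1e-12)
        assert len(st.history) == st.k
        assert st.residual == st.history[-1]

    def test_identity_stops_immediately(self, rng):
        x0 = rng.standard_normal(5)
        st = iterate_to_fixed_point(lambda x: x, x0, 1e-9, 50)
        assert st.k == 1 and st.residual == 0.0
        np.testing.assert_array_equal(st.x, x0)

    def test_averaged_random_contraction(self, rng):
        # T = (1-a)I + aQ with Q a 0.9-contraction converges (Banach)
        for seed in range(5):
            r = np.random.default_rng(seed)
            B = r.standard_normal((6, 6))
            B *= 0.9 / np.linalg.norm(B, 2)
            b = r.standard_normal(6)
            Q = lambda x: B @ x + b
            T = lambda x: 0.5 * x + 0.5 * Q(x)
            st = iterate_to_fixed_point(T, np.zeros(6), 1e-10, 2000)
            assert st.converged
            assert np.linalg.norm(T(st.x) - st.x) <= 2 * 1e-10 * (1 + np.linalg.norm(st.x))

    def test_residuals_decrease_for_averaged_maps(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            B = r.standard_normal((8, 8))
            B /= np.linalg.norm(B, 2)  # exactly 1-Lipschitz
            T = lambda x: 0.5 * x + 0.5 * (B @ x + 1.0)
            st = iterate_to_fixed_point(T, np.zeros(8), 1e-300, 201)
            later = st.history[199] if st.k > 199 else st.history[-1]
            assert later < st.history[19]

    def test_divergence_raises_with_index(self):
        with pytest.raises(DivergenceError) as err:
            iterate_to_fixed_point(lambda x: x * 1e200, np.array([1.0]), 1e-6, 10)
        assert err.value.k >= 1

    def test_invalid_tol(self):
        with pytest.raises(ValueError):
            iterate_to_fixed_point(lambda x: x, np.zeros(2), 0.0, 5)


class TestPgOperator:
    def test_one_step_reaches_data(self, rng):
        I = make_matrix_map(np.eye(4))
        d = rng.standard_normal(4)
        T = make_pg_operator(I, I, d, 0.0)
        np.testing.assert_allclose(T(rng.standard_normal(4)), d, atol=1e-14)

    def test_least_squares_stationarity(self, rng):
        A = rng.standard_normal((4, 6)) / 2
        Am = make_matrix_map(A)
        c = 0.9 / Am.norm_bound ** 2
        W = make_matrix_map(c * A.T)
        d = rng.standard_normal(4)
        T = make_pg_operator(W, Am, d, 0.0)
        st = iterate_to_fixed_point(T, np.zeros(6), 1e-12, 20000)
        # fixed points with theta=0 satisfy the normal equations
        np.testing.assert_allclose(A.T @ (A @ st.x - d), 0, atol=1e-8)

    def test_matches_handrolled_ista(self, rng, ista_oracle):
        A = rng.standard_normal((2, 3))
        Am = make_matrix_map(A)
        step = 0.5 / Am.norm_bound ** 2
        tau = 0.3
        d = rng.standard_normal(2)
        T = make_pg_operator(make_matrix_map(step * A.T), Am, d, step * tau)
        x = np.zeros(3)
        ref = ista_oracle(A, d, step, tau, 25)
        for k in range(25):
            x = T(x)
            np.testing.assert_allclose(x, ref[k], atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        A = make_matrix_map(rng.standard_normal((4, 6)))
        W = make_matrix_map(rng.standard_normal((5, 4)))
        with pytest.raises(ValueError):
            make_pg_operator(W, A, np.zeros(4), 0.1)


class TestLadmm:
    def test_fixed_point_unchanged(self, rng):
        # prox_f = prox_h = identity, K = M = I, delta = 0, start at solution
        I = make_matrix_map(np.eye(3))
        d = rng.standard_normal(3)
        prob = make_ladmm_problem(I, I, d, 0.0, prox_f=lambda v, t: v)
        state = LadmmState(p=d.copy(), w=d.copy(), nu1=np.zeros(3),
                          nu2=np.zeros(3), x=d.copy())
        out = ladmm_step(state, prob)
        for a, b in zip((out.p, out.w, out.nu1, out.nu2, out.x),
                        (d, d, np.zeros(3), np.zeros(3), d)):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_step_side_effect_free(self, rng):
        I = make_matrix_map(np.eye(3))
        prob = make_ladmm_problem(I, I, rng.standard_normal(3), 0.0,
                                  prox_f=lambda v, t: prox_l1(v, t))
        state = initial_ladmm_state(prob, rng.standard_normal(3))
        before = state.copy()
        ladmm_step(state, prob)
        for a, b in zip((state.p, state.w, state.nu1, state.nu2, state.x),
                        (before.p, before.w, before.nu1, before.nu2, before.x)):
            np.testing.assert_array_equal(a, b)

    def test_tiny_basis_pursuit_vertex(self):
        # min ||x||_1 s.t. 2x1 + x2 = 2 has unique minimizer (1, 0)
        K = make_matrix_map(np.eye(2))
        M = make_matrix_map(np.array([[2.0, 1.0]]))
        prob = make_ladmm_problem(K, M, np.array([2.0]), 0.0,
                                  prox_f=lambda v, t: prox_l1(v, t))
        st = ladmm_solve(prob, np.zeros(2), 1e-10, 20000)
        np.testing.assert_allclose(st.x, [1.0, 0.0], atol=1e-4)

    def test_matches_lp_oracle(self, rng, bp_oracle):
        for _ in range(5):
            A = rng.standard_normal((8, 20)) / np.sqrt(8)
            xs = np.zeros(20)
            xs[rng.choice(20, 3, replace=False)] = rng.standard_normal(3)
            d = A @ xs
            ref = bp_oracle(A, d)
            prob = make_ladmm_problem(make_matrix_map(np.eye(20)),
                                      make_matrix_map(A), d, 0.0,
                                      prox_f=lambda v, t: prox_l1(v, t))
            st = ladmm_solve(prob, np.zeros(20), 1e-10, 20000)
            assert np.linalg.norm(st.x - ref) / np.linalg.norm(ref) < 1e-3

    def test_feasibility_forced_when_delta_zero(self, rng):
        I = make_matrix_map(np.eye(4))
        d = rng.standard_normal(4)
        prob = make_ladmm_problem(I, I, d, 0.0,
                                  prox_f=lambda v, t: prox_l1(v, 0.0))
        st = ladmm_solve(prob, np.zeros(4), 1e-12, 5000)
        np.testing.assert_allclose(st.x, d, atol=1e-6)

    def test_unconverged_flagged_not_fatal(self, rng):
        A = rng.standard_normal((8, 20))
        prob = make_ladmm_problem(make_matrix_map(np.eye(20)),
                                  make_matrix_map(A), rng.standard_normal(8),
                                  0.0, prox_f=lambda v, t: prox_l1(v, t))
        st = ladmm_solve(prob, np.zeros(20), 1e-14, 5)
        assert not st.converged and st.k == 5

    def test_row_permutation_invariance(self, rng, bp_oracle):
        A = rng.standard_normal((6, 15)) / 2
        xs = np.zeros(15)
        xs[rng.choice(15, 2, replace=False)] = rng.standard_normal(2)
        d = A @ xs
        perm = rng.permutation(6)
        K = make_matrix_map(np.eye(15))
        p1 = make_ladmm_problem(K, make_matrix_map(A), d, 0.0,
                                prox_f=lambda v, t: prox_l1(v, t))
        p2 = make_ladmm_problem(K, make_matrix_map(A[perm]), d[perm], 0.0,
                                prox_f=lambda v, t: prox_l1(v, t))
        s1 = ladmm_solve(p1, np.zeros(15), 1e-11, 30000)
        s2 = ladmm_solve(p2, np.zeros(15), 1e-11, 30000)
        np.testing.assert_allclose(s1.x, s2.x, atol=1e-6)

    def test_feasibility_decreases_over_windows(self, rng):
        # with delta=0 and consistent data, ||Mx - d|| trends to zero:
        # compare window means 50 iterations apart
        A = rng.standard_normal((6, 15)) / 2
        d = A @ rng.standard_normal(15)
        prob = make_ladmm_problem(make_matrix_map(np.eye(15)),
                                  make_matrix_map(A), d, 0.0,
                                  prox_f=lambda v, t: prox_l1(v, t))
        state = initial_ladmm_state(prob, np.zeros(15))
        feas = []
        for _ in range(400):
            state = ladmm_step(state, prob)
            feas.append(np.linalg.norm(A @ state.x - d))
        windows = [np.mean(feas[i:i + 50]) for i in range(0, 400, 50)]
        assert all(a > b for a, b in zip(windows, windows[1:]))

    def test_trace_written_as_csv(self, rng, tmp_path):
        from implicitl2o.solvers import write_trace
        I = make_matrix_map(np.eye(4))
        prob = make_ladmm_problem(I, I, rng.standard_normal(4), 0.0,
                                  prox_f=lambda v, t: prox_l1(v, t))
        st = ladmm_solve(prob, np.zeros(4), 1e-8, 500)
        path = tmp_path / "trace.csv"
        write_trace(st, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "k,residual"
        assert len(lines) == st.k + 1

    def test_batched_matches_loop(self, rng):
        A = rng.standard_normal((5, 12)) / 2
        D = rng.standard_normal((5, 3))
        K = make_matrix_map(np.eye(12))
        singles = []
        for j in range(3):
            prob = make_ladmm_problem(K, make_matrix_map(A), D[:, j], 0.0,
                                      prox_f=lambda v, t: prox_l1(v, t))
            singles.append(ladmm_solve(prob, np.zeros(12), 1e-10, 20000).x)
        prob = make_ladmm_problem(K, make_matrix_map(A), D, 0.0,
                                  prox_f=lambda v, t: prox_l1(v, t))
        batched = ladmm_solve(prob, np.zeros((12, 3)), 1e-11, 40000).x
        np.testing.assert_allclose(batched, np.column_stack(singles), atol=1e-5)
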
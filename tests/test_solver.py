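"""Proximal operators, the x-update and the full ADMM iteration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nbcnv.core import SolverConfig, ValidationError
from nbcnv.solver import (admm_fit, apply_G, objective, prox_l1,
                          prox_l1_centered, prox_nb_fidelity,
                          prox_poisson_fidelity, prox_positive,
                          solve_x_subproblem)


def grid_minimize(fun, lo, hi, stages=3, points=20_001):
    """Staged grid search reaching ~1e-6 resolution on [lo, hi]."""
    lo0, hi0 = lo, hi
    for _ in range(stages):
        xs = np.linspace(lo, hi, points)
        vals = fun(xs)
        i = int(np.nanargmin(vals))
        span = (hi - lo) / (points - 1)
        lo, hi = max(xs[i] - span, lo0), min(xs[i] + span, hi0)
    return 0.5 * (lo + hi)


class TestScalarProxes:
    def test_prox_positive(self):
        assert prox_positive(-1.0) == 0.0
        assert prox_positive(2.5) == 2.5
        assert prox_positive(0.0) == 0.0

    def test_prox_l1(self):
        assert prox_l1(3.0, 1.0) == 2.0
        assert prox_l1(-0.5, 1.0) == 0.0
        assert prox_l1(-3.0, 1.0) == -2.0

    def test_prox_l1_centered(self):
        c = 4.2
        assert prox_l1_centered(c, 0.7, c) == c
        assert prox_l1_centered(c + 3, 1.0, c) == pytest.approx(c + 2)

    def test_nb_prox_fixed_point_at_data(self):
        # v = y is stationary for any dispersion/penalty
        assert prox_nb_fidelity(7.0, 7, 9.5, 0.37) == pytest.approx(7.0, abs=1e-9)

    def test_nb_prox_golden_ratio_case(self):
        # y=0, a=1, penalty=1, v=2: stationarity reduces to z^2 - z - 1 = 0
        z = prox_nb_fidelity(2.0, 0, 1.0, 1.0)
        assert z == pytest.approx((1 + np.sqrt(5)) / 2, abs=1e-9)

    def test_nb_prox_large_penalty_returns_v(self):
        assert prox_nb_fidelity(3.7, 10, 9.5, 1e6) == pytest.approx(3.7, abs=1e-4)

    def test_poisson_prox_closed_form(self):
        assert prox_poisson_fidelity(3.0, 0, 1.0) == pytest.approx(2.0)
        assert prox_poisson_fidelity(1.0, 4, 1.0) == pytest.approx(2.0)


class TestProxGridOracles:
    """Each prox must agree with a staged grid search of its objective."""

    def test_nb_prox_matches_grid(self, rng):
        for _ in range(60):
            v = rng.uniform(-2, 15)
            y = int(rng.integers(0, 40))
            a = rng.uniform(0.3, 30)
            mu = rng.uniform(0.05, 10)
            z = prox_nb_fidelity(v, y, a, mu)
            zg = grid_minimize(
                lambda t: (y + a) * np.log(t + a) - y * np.log(t)
                + 0.5 * mu * (t - v) ** 2,
                1e-9, max(abs(v), y, 1.0) * 3 + 5)
            assert z == pytest.approx(zg, abs=1e-5)

    def test_nb_prox_with_scale_matches_grid(self, rng):
        for _ in range(20):
            v = rng.uniform(0.1, 3)
            y = int(rng.integers(0, 400))
            a, mu, s = rng.uniform(2, 20), rng.uniform(0.2, 5), rng.uniform(50, 300)
            z = prox_nb_fidelity(v, y, a, mu, scale=s)
            zg = grid_minimize(
                lambda t: (y + a) * np.log(s * t + a) - y * np.log(t)
                + 0.5 * mu * (t - v) ** 2,
                1e-9, max(abs(v), y / s, 1.0) * 3 + 5)
            assert z == pytest.approx(zg, abs=1e-5)

    def test_poisson_prox_matches_grid(self, rng):
        for _ in range(40):
            v = rng.uniform(-2, 10)
            y = int(rng.integers(0, 30))
            mu = rng.uniform(0.05, 8)
            z = prox_poisson_fidelity(v, y, mu)
            zg = grid_minimize(
                lambda t: t - y * np.log(t) + 0.5 * mu * (t - v) ** 2,
                1e-9, max(abs(v), y, 1.0) * 3 + 5)
            assert z == pytest.approx(zg, abs=1e-5)

    def test_centered_l1_matches_grid(self, rng):
        for _ in range(40):
            v, thr, c = rng.uniform(-5, 5), rng.uniform(0, 3), rng.uniform(-2, 2)
            z = prox_l1_centered(v, thr, c)
            zg = grid_minimize(
                lambda t: thr * np.abs(t - c) + 0.5 * (t - v) ** 2, -10, 10)
            assert z == pytest.approx(zg, abs=1e-5)


class TestXSubproblem:
    def test_n1_is_mean_of_three_targets(self):
        ud = np.array([3.0, 6.0, 9.0])  # blocks (1,1,0,1)
        assert solve_x_subproblem(ud, 1) == pytest.approx(np.array([6.0]))

    @pytest.mark.parametrize("n", [2, 3, 5, 17, 50])
    def test_matches_dense_solve(self, n, rng):
        ud = rng.normal(size=4 * n - 1)
        D = np.diff(np.eye(n), axis=0)
        G = np.vstack([np.eye(n)] * 2 + [D, np.eye(n)])
        dense = np.linalg.solve(G.T @ G, G.T @ ud)
        assert np.max(np.abs(solve_x_subproblem(ud, n) - dense)) < 1e-10

    def test_recovers_consistent_target(self, rng):
        x_star = rng.uniform(0.5, 4, 9)
        assert np.max(np.abs(solve_x_subproblem(apply_G(x_star), 9) - x_star)) < 1e-10

    def test_rejects_empty(self):
        with pytest.raises(ValidationError):
            solve_x_subproblem(np.zeros(0), 0)


class TestObjective:
    def test_barrier_semantics(self):
        cfg = SolverConfig(dispersion=2.0)
        assert objective([1.0, -0.5], [1, 2], cfg) == np.inf

    def test_penalties_vanish_at_constant_baseline(self):
        y = np.array([5.0, 5.0, 5.0])
        cfg = SolverConfig(lambda1=3.0, lambda2=4.0, dispersion=2.0,
                           baseline_c=5.0, signal_scale=1.0)
        x = np.full(3, 5.0)
        a = 2.0
        fid = np.sum((y + a) * np.log(x + a) - y * np.log(x))
        assert objective(x, y, cfg) == pytest.approx(fid, abs=1e-12)

    def test_matches_independent_formula(self, rng):
        y = rng.integers(1, 20, 6).astype(float)
        x = rng.uniform(0.5, 20, 6)
        cfg = SolverConfig(lambda1=1.3, lambda2=0.7, dispersion=4.0,
                           baseline_c=8.0, signal_scale=2.0)
        a, c, s = 4.0, 8.0, 2.0
        expected = sum((yt + a) * np.log(xt + a) - yt * np.log(xt)
                       for xt, yt in zip(x, y))
        expected += (1.3 / s) * sum(abs(x[i + 1] - x[i]) for i in range(5))
        expected += (0.7 / s) * sum(abs(xt - c) for xt in x)
        assert objective(x, y, cfg) == pytest.approx(expected, abs=1e-10)


def coordinate_descent(y, cfg, sweeps=300):
    """Brute-force minimizer: cyclic 1-D staged-grid descent."""
    x = np.maximum(y.astype(float), 0.5)
    hi = max(float(y.max()), 1.0) * 2 + 5
    best = objective(x, y, cfg)
    for _ in range(sweeps):
        improved = False
        for i in range(len(x)):
            lo, up = 1e-6, hi
            for _ in range(4):
                grid = np.linspace(lo, up, 2001)
                vals = np.empty_like(grid)
                xi = x.copy()
                for g, gval in enumerate(grid):
                    xi[i] = gval
                    vals[g] = objective(xi, y, cfg)
                j = int(np.argmin(vals))
                span = (up - lo) / 2000
                lo, up = max(grid[j] - span, 1e-9), grid[j] + span
            x[i] = 0.5 * (lo + up)
        val = objective(x, y, cfg)
        if best - val < 1e-10:
            improved = False
        else:
            improved = True
        best = val
        if not improved:
            break
    return x, best


class TestADMM:
    def test_near_interpolation_at_vanishing_penalties(self):
        y = np.array([5.0] * 10 + [12.0] * 8 + [5.0] * 10)
        cfg = SolverConfig(lambda1=1e-6, lambda2=1e-6, dispersion=5.0,
                           signal_scale=1.0, tol=1e-9, max_iter=20_000)
        x, state = admm_fit(y, cfg)
        assert np.max(np.abs(x - y)) / y.max() < 0.01

    def test_dominant_sparsity_pins_to_baseline(self, rng):
        y = rng.poisson(60, 50).astype(float)
        cfg = SolverConfig(lambda1=0.0, lambda2=1e6, dispersion=9.5,
                           tol=1e-8, max_iter=20_000)
        x, _ = admm_fit(y, cfg)
        c = y.mean()
        assert np.max(np.abs(x - c)) / c < 1e-3

    def test_reversal_equivariance(self, rng):
        y = rng.poisson(50, 60).astype(float)
        y[20:30] *= 2
        cfg = SolverConfig(dispersion=9.5, tol=1e-9, max_iter=30_000)
        x_fwd, _ = admm_fit(y, cfg)
        x_rev, _ = admm_fit(y[::-1].copy(), cfg)
        assert np.max(np.abs(x_fwd - x_rev[::-1])) < 1e-4

    def test_nb_limit_matches_poisson_solver(self, rng):
        y = rng.poisson(30, 40).astype(float)
        base = dict(lambda1=0.8, lambda2=0.5, tol=1e-10, max_iter=50_000,
                    signal_scale=1.0, baseline_c=float(y.mean()))
        x_nb, _ = admm_fit(y, SolverConfig(dispersion=1e8, **base))
        x_po, _ = admm_fit(y, SolverConfig(dispersion=1.0,
                                           fidelity="poisson", **base))
        assert np.max(np.abs(x_nb - x_po)) < 1e-3

    def test_final_iterate_positive_and_residuals_small(self, rng):
        y = rng.poisson(25, 80).astype(float)
        y[::7] = 0  # include zero-count bins
        cfg = SolverConfig(dispersion=3.0, tol=1e-7, max_iter=30_000)
        x, state = admm_fit(y, cfg)
        assert np.all(x > 0)
        assert state.converged
        assert state.primal_residual / np.sqrt(4 * len(y) - 1) < 1e-6

    @pytest.mark.parametrize("fidelity", ["negative_binomial", "poisson"])
    @pytest.mark.parametrize("n", [2, 4, 5])
    def test_objective_matches_bruteforce(self, n, fidelity, rng):
        y = rng.integers(1, 15, n).astype(float)
        cfg = SolverConfig(lambda1=1.0, lambda2=1.0, dispersion=2.0,
                           fidelity=fidelity, signal_scale=1.0,
                           baseline_c=float(y.mean()),
                           tol=1e-12, max_iter=100_000)
        x_admm, _ = admm_fit(y, cfg)
        _, f_cd = coordinate_descent(y, cfg)
        assert objective(x_admm, y, cfg) <= f_cd + 1e-4

    def test_rejects_bad_input(self):
        cfg = SolverConfig(dispersion=1.0)
        with pytest.raises(ValidationError):
            admm_fit(np.array([1.0, -2.0]), cfg)
        with pytest.raises(ValidationError):
            admm_fit(np.zeros(0), cfg)


@given(st.integers(0, 1000))
def test_prox_l1_shrinks_toward_zero(seed):
    r = np.random.default_rng(seed)
    v = r.normal(scale=5)
    t = r.uniform(0, 3)
    z = prox_l1(v, t)
    assert abs(z) <= abs(v) + 1e-12
    assert z * v >= 0
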
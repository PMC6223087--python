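"""Constrained least-squares solver menu and the UPSO search."""

import numpy as np
import pytest
import scipy.optimize

from deblend.solvers import UpsoConfig, bounded_lsq, nnls, upso_minimize


class TestNnls:
    def test_projects_onto_nonnegative_orthant(self):
        x = nnls(np.eye(2), np.array([1.0, -1.0]))
        np.testing.assert_allclose(x, [1.0, 0.0], atol=1e-12)

    def test_feasible_target_reached_exactly(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(0, 2, size=(6, 3))
        x_true = rng.uniform(0.1, 1, size=3)
        x = nnls(M, M @ x_true)
        assert np.linalg.norm(M @ x - M @ x_true) < 1e-10

    def test_agrees_with_quadratic_programming_route(self):
        # same problem as QP: min 1/2 x^T (M^T M) x - (M^T b)^T x, x >= 0
        rng = np.random.default_rng(1)
        M = rng.normal(size=(8, 4))
        b = rng.normal(size=8)
        x_nnls = nnls(M, b)
        res = scipy.optimize.minimize(
            lambda x: 0.5 * x @ (M.T @ M) @ x - (M.T @ b) @ x,
            np.ones(4), jac=lambda x: (M.T @ M) @ x - M.T @ b,
            bounds=[(0, None)] * 4, method="L-BFGS-B",
            options={"ftol": 1e-15, "gtol": 1e-12})
        np.testing.assert_allclose(x_nnls, res.x, atol=1e-6)
        assert np.sum((M @ x_nnls - b) ** 2) <= np.sum((M @ res.x - b) ** 2) + 1e-8


class TestBoundedLsq:
    def test_clipped_one_dimensional_optimum(self):
        # (2x - 1)^2 minimized at 0.5, clipped by the active bound 0.3
        x = bounded_lsq(np.array([[2.0]]), np.array([1.0]), 0.0, 0.3)
        assert x[0] == pytest.approx(0.3, abs=1e-12)

    def test_vacuous_bounds_equal_ordinary_least_squares(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(7, 3))
        b = rng.normal(size=7)
        x = bounded_lsq(M, b, -np.inf, np.inf)
        expected = np.linalg.lstsq(M, b, rcond=None)[0]
        np.testing.assert_allclose(x, expected, atol=1e-10)

    def test_pinned_bounds_return_lb(self):
        lb = np.array([0.2, 0.7])
        x = bounded_lsq(np.eye(2), np.array([5.0, 5.0]), lb, lb)
        np.testing.assert_array_equal(x, lb)

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            bounded_lsq(np.eye(2), np.ones(2), np.array([1.0, 1.0]),
                        np.array([0.0, 2.0]))


class TestUpso:
    def test_convex_quadratic_reaches_optimum(self):
        x0 = np.array([0.3, -0.7])
        x = upso_minimize(lambda z: float(np.sum((z - x0) ** 2)),
                          [-2.0, -2.0], [2.0, 2.0], UpsoConfig(seed=1))
        assert np.max(np.abs(x - x0)) < 1e-3

    def test_stage1_objective_matches_nnls(self):
        M = np.array([[6.0, 3.0], [8.0, 14.0]]).T
        b = np.ones(2)
        d_nnls = nnls(M, b)
        f_nnls = float(np.sum((M @ d_nnls - b) ** 2))
        d_upso = upso_minimize(lambda z: float(np.sum((M @ z - b) ** 2)),
                               [0.0, 0.0], [1.0, 1.0], UpsoConfig(seed=1))
        f_upso = float(np.sum((M @ d_upso - b) ** 2))
        assert abs(f_upso - f_nnls) < 1e-3

    def test_deterministic_and_inside_bounds(self):
        cfg = UpsoConfig(seed=7, iterations=50)
        obj = lambda z: float(np.sum(z ** 2) + np.sin(z).sum())
        lo, hi = np.array([-1.0, 0.5]), np.array([1.0, 2.0])
        x1 = upso_minimize(obj, lo, hi, cfg)
        x2 = upso_minimize(obj, lo, hi, cfg)
        np.testing.assert_array_equal(x1, x2)
        assert np.all(x1 >= lo) and np.all(x1 <= hi)

    @pytest.mark.parametrize("u,uses", [(1.0, "global"), (0.0, "local")])
    def test_unification_extremes_match_pure_variants(self, u, uses):
        """u=1 is the pure swarm-best variant, u=0 the pure ring variant."""
        rng_obj = lambda z: float(np.sum((z - 0.25) ** 2))
        lo, hi = np.array([-1.0]), np.array([1.0])
        cfg = UpsoConfig(seed=3, iterations=40, unification_u=u)
        x = upso_minimize(rng_obj, lo, hi, cfg)
        x_ref = _pure_pso_reference(rng_obj, lo, hi, cfg, variant=uses)
        np.testing.assert_allclose(x, x_ref, atol=1e-12)


def _pure_pso_reference(objective, lb, ub, config, variant):
    """Independently coded single-variant PSO sharing the rng draw pattern."""
    lb, ub = np.atleast_1d(lb), np.atleast_1d(ub)
    r = lb.size
    width = ub - lb
    rng = np.random.default_rng(config.seed)
    n = config.swarm_size
    x = lb + rng.random((n, r)) * width
    v = (rng.random((n, r)) - 0.5) * width
    pbest, pbest_f = x.copy(), np.array([objective(xi) for xi in x])
    chi, c1, c2 = config.constriction_chi, config.c1, config.c2
    for _ in range(config.iterations):
        g = int(np.argmin(pbest_f))
        nb = np.empty(n, dtype=int)
        for i in range(n):
            idx = [(i + d) % n for d in
                   range(-config.neighborhood_radius, config.neighborhood_radius + 1)]
            nb[i] = idx[int(np.argmin(pbest_f[idx]))]
        r1, r2 = rng.random((n, r)), rng.random((n, r))
        r3, r4 = rng.random((n, r)), rng.random((n, r))
        if variant == "global":
            v = chi * (v + c1 * r1 * (pbest - x) + c2 * r2 * (pbest[g] - x))
        else:
            v = chi * (v + c1 * r3 * (pbest - x) + c2 * r4 * (pbest[nb] - x))
        v = np.clip(v, -width, width)
        x = np.clip(x + v, lb, ub)
        f = np.array([objective(xi) for xi in x])
        improved = f < pbest_f
        pbest[improved], pbest_f[improved] = x[improved], f[improved]
    return pbest[int(np.argmin(pbest_f))]
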
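import numpy as np
import pytest

from lqreg import (
    Coefficients,
    Dataset,
    PenaltySpec,
    QSpec,
    fit,
    fit_lq,
    fit_path,
    lambda_for_least_squares,
    lambda_grid,
    lasso_kkt_violation,
    lq_likelihood,
    mlqe,
    penalty_value,
    prox,
    standardize,
)
from lqreg.solver import _cd_solve
from conftest import make_dataset


class TestStandardize:
    def test_three_point_column(self):
        data, _ = standardize(np.array([[1.0], [2.0], [3.0]]), np.zeros(3))
        np.testing.assert_allclose(
            data.X[:, 1], [-1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)], atol=1e-12
        )

    def test_idempotent(self, rng):
        X = rng.standard_normal((20, 4))
        d1, _ = standardize(X, np.zeros(20))
        d2, _ = standardize(d1.X[:, 1:], np.zeros(20))
        np.testing.assert_allclose(d1.X, d2.X, atol=1e-12)

    def test_zero_variance_column_named(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            standardize(X, np.zeros(5))

    def test_destandardized_coefficients_reproduce_fitted_values(self, rng):
        X = rng.standard_normal((30, 3)) * [1.0, 10.0, 0.1] + [5.0, -2.0, 0.0]
        y = X @ [1.0, 0.5, -2.0] + rng.standard_normal(30)
        data, transform = standardize(X, y)
        theta = mlqe(data)
        fitted_std = data.X @ theta.as_array()
        orig = transform.destandardize(theta)
        fitted_orig = orig.intercept + X @ orig.slopes
        np.testing.assert_allclose(fitted_std, fitted_orig, atol=1e-9)


class TestLambdaGrid:
    def test_length_and_log_spacing(self):
        data = make_dataset(n=40, d=5, seed=1, slopes=[1, 0, 0, 2, 0])
        grid = lambda_grid(data, nlambda=60)
        assert len(grid) == 60
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    def test_min_ratio_defaults(self):
        tall = make_dataset(n=50, d=5, seed=2)
        wide = make_dataset(n=10, d=20, seed=3)
        g1 = lambda_grid(tall)
        g2 = lambda_grid(wide)
        assert g1[-1] / g1[0] == pytest.approx(0.001, rel=1e-9)
        assert g2[-1] / g2[0] == pytest.approx(0.05, rel=1e-9)

    @pytest.mark.parametrize("family", ["lasso", "scad", "mcp"])
    def test_all_slopes_zero_at_lambda_max(self, family):
        data = make_dataset(n=50, d=6, seed=4, slopes=[3, 0, -2, 0, 0, 1])
        grid = lambda_grid(data, family=family)
        coef = fit(data, PenaltySpec(family, float(grid[0])))
        np.testing.assert_allclose(coef.slopes, 0.0, atol=1e-10)
        assert coef.intercept == pytest.approx(data.y.mean(), abs=1e-10)


class TestFit:
    def test_lambda_zero_is_ols(self):
        data = make_dataset(n=30, d=4, seed=5, slopes=[1, -2, 0, 0])
        for family in ("lasso", "scad", "mcp"):
            coef = fit(data, PenaltySpec(family, 0.0), tol=1e-12)
            np.testing.assert_allclose(
                coef.as_array(), mlqe(data).as_array(), atol=1e-6
            )

    def test_orthonormal_design_closed_form(self, rng):
        # orthonormalized centered columns: coordinate solutions decouple into
        # the weighted prox of x_j' y with penalty weight n
        n, d = 40, 4
        raw = rng.standard_normal((n, d))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = np.column_stack([np.ones(n), Q])
        y = Q @ np.array([2.0, -1.0, 0.0, 0.5]) + 0.1 * rng.standard_normal(n) + 1.0
        data = Dataset(X, y)
        for family in ("lasso", "scad", "mcp"):
            spec = PenaltySpec(family, 0.01)
            coef = fit(data, spec, tol=1e-12)
            z = Q.T @ y
            expected = np.array([prox(zj, spec, weight=n) for zj in z])
            np.testing.assert_allclose(coef.slopes, expected, atol=1e-8)
            assert coef.intercept == pytest.approx(y.mean(), abs=1e-8)

    def test_lasso_beats_dense_grid(self):
        # global optimality on a 2-d problem vs a brute-force grid search
        data = make_dataset(n=20, d=2, seed=6, slopes=[1.0, -0.5])
        spec = PenaltySpec("lasso", 0.02)
        coef = fit(data, spec, tol=1e-12)

        def objective(icpt, s1, s2):
            r = data.y - icpt - data.X[:, 1] * s1 - data.X[:, 2] * s2
            return 0.5 * r @ r / data.n + penalty_value([s1, s2], spec)

        icpt = coef.intercept
        grid = np.arange(-3, 3.001, 0.01)
        best = min(objective(icpt, s1, s2) for s1 in grid for s2 in grid)
        ours = objective(icpt, *coef.slopes)
        assert ours <= best + 1e-12

    def test_lasso_kkt_conditions(self):
        for seed in range(5):
            data = make_dataset(n=35, d=6, seed=seed, slopes=[2, -1, 0, 0, 1, 0])
            lam = float(lambda_grid(data)[30])
            coef = fit(data, PenaltySpec("lasso", lam), tol=1e-12)
            assert lasso_kkt_violation(data, coef, lam) < 1e-6

    @pytest.mark.parametrize("family", ["lasso", "scad", "mcp"])
    def test_objective_monotone_per_sweep(self, family):
        data = make_dataset(n=30, d=5, seed=7, slopes=[2, 0, -2, 0, 1])
        lam = float(lambda_grid(data, family=family)[50])
        spec = PenaltySpec(family, lam)
        _, _, _, objs = _cd_solve(
            data.X, data.y, spec, 1.0, np.zeros(6), 1e-10, 10_000
        )
        assert np.all(np.diff(objs) <= 1e-12)


class TestFitPath:
    def test_path_length_and_warm_start_continuity(self):
        data = make_dataset(n=60, d=8, seed=8, slopes=[3, 3, 0, 0, 0, 0, 0, 0])
        path = fit_path(data, "lasso", nlambda=100)
        assert len(path) == 100
        coefs = path.coef_matrix()
        jumps = np.abs(np.diff(coefs, axis=0)).max(axis=1)
        assert jumps.max() < 1.0  # no oscillation between adjacent lambdas

    def test_small_lambda_end_near_ols(self):
        # the residual soft-threshold bias at the path end is ~ lambda_max *
        # min_ratio * n, so the 1e-3 agreement needs O(1)-scale correlations
        data = make_dataset(n=200, d=3, seed=9, slopes=[0.3, -0.2, 0.4], noise_scale=0.3)
        path = fit_path(data, "lasso", min_ratio=0.001)
        np.testing.assert_allclose(
            path.coefs[-1].as_array(), mlqe(data).as_array(), atol=1e-3
        )

    def test_rejects_increasing_grid(self):
        data = make_dataset(n=20, d=2, seed=10)
        with pytest.raises(ValueError):
            fit_path(data, "lasso", lambdas=np.array([0.1, 0.2]))


class TestLqEquivalence:
    """Lq-objective fits coincide with penalized least squares after the lambda map."""

    @pytest.mark.parametrize("q", [1.0, 1.5, 2.0, 2.5])
    def test_lasso_lambda_mapping(self, q):
        data = make_dataset(n=40, d=5, seed=11, slopes=[2, 0, -1, 0, 0], q_noise=q)
        qspec = QSpec(q)
        lam = 0.05
        via_lq = fit_lq(data, PenaltySpec("lasso", lam), qspec, tol=1e-12)
        lam_ls = lambda_for_least_squares(lam, qspec)
        assert lam_ls == pytest.approx(lam * (3 - q) / (2 * qspec.Zq ** (q - 1)))
        via_ls = fit(data, PenaltySpec("lasso", lam_ls), tol=1e-12)
        np.testing.assert_allclose(via_lq.as_array(), via_ls.as_array(), atol=1e-8)

    @pytest.mark.parametrize("q", [1.5, 2.0])
    def test_mcp_mapping_with_gamma_rescale(self, q):
        data = make_dataset(n=40, d=4, seed=12, slopes=[3, 0, 0, -3], q_noise=q)
        qspec = QSpec(q)
        c = 2 * qspec.Zq ** (q - 1) / (3 - q)
        lam = 0.05
        via_lq = fit_lq(data, PenaltySpec("mcp", lam, gamma=3.0), qspec, tol=1e-12)
        via_ls = fit(data, PenaltySpec("mcp", lam / c, gamma=3.0 * c), tol=1e-12)
        np.testing.assert_allclose(via_lq.as_array(), via_ls.as_array(), atol=1e-8)

    def test_lambda_zero_lq_fit_is_mlqe(self):
        data = make_dataset(n=30, d=3, seed=13, slopes=[1, 2, 3], q_noise=2.0)
        qspec = QSpec(2.0)
        coef = fit_lq(data, PenaltySpec("lasso", 0.0), qspec, tol=1e-12)
        np.testing.assert_allclose(coef.as_array(), mlqe(data).as_array(), atol=1e-6)

    @pytest.mark.parametrize("q", [1.5, 2.5])
    def test_lq_objective_value_decreases_from_start(self, q):
        # sanity: the fitted point has higher Lq-likelihood than the null fit
        data = make_dataset(n=30, d=3, seed=14, slopes=[2, 0, -2], q_noise=q)
        qspec = QSpec(q)
        coef = fit_lq(data, PenaltySpec("lasso", 0.01), qspec)
        null = Coefficients(float(data.y.mean()), np.zeros(3))
        assert lq_likelihood(coef, data, qspec) > lq_likelihood(null, data, qspec)
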
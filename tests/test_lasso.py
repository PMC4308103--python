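"""LASSO solutions (KKT, closed forms), the path, and BIC selection."""

import numpy as np
import pytest

import cytovar as cv
from cytovar.lasso import LassoFit, LassoPath

from conftest import random_design


def sdesign(X, y):
    """Wrap pre-standardized arrays directly (unit tests control scaling)."""
    X = np.asarray(X, float)
    names = ("X1", "X2", "X1X2", "X4")[: X.shape[1]]
    return cv.StandardizedDesign(X, np.asarray(y, float), names,
                                 np.zeros(X.shape[1]), np.ones(X.shape[1]), 0.0)


def std_random(rng, n, p):
    d = random_design(rng, n, p)
    return cv.standardize(d)


class TestLambdaMax:
    def test_single_unit_norm_predictor(self):
        x = np.zeros(9)
        x[0] = 1.0          # unit norm
        y = 3.0 * x
        assert cv.lambda_max(sdesign(x[:, None], y)) == pytest.approx(6.0)

    def test_orthogonal_response(self):
        x = np.array([1.0, -1.0, 0.0])
        y = np.array([1.0, 1.0, -2.0])
        assert cv.lambda_max(sdesign(x[:, None], y)) == pytest.approx(0.0)

    def test_duplicate_strongest_predictor_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 2))
        y = rng.standard_normal(12)
        base = cv.lambda_max(sdesign(X, y))
        j = int(np.argmax(np.abs(X.T @ y)))
        X2 = np.column_stack([X, X[:, j]])
        assert cv.lambda_max(sdesign(X2, y)) == pytest.approx(base)

    def test_all_fits_null_at_lambda_max(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            sd = std_random(rng, 15, 3)
            fit = cv.fit_lasso(sd, cv.lambda_max(sd))
            assert fit.support == frozenset()
            assert np.all(fit.beta == 0.0)


class TestFitLasso:
    def test_single_predictor_closed_form(self):
        x = np.zeros(9)
        x[0] = 1.0
        y = 3.0 * x
        fit = cv.fit_lasso(sdesign(x[:, None], y), lam=2.0)
        assert fit.beta[0] == pytest.approx(2.0)   # (|x'y| - lam/2)/x'x

    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(11)
        sd = std_random(rng, 20, 3)
        fit = cv.fit_lasso(sd, 0.0)
        beta = np.linalg.solve(sd.X.T @ sd.X, sd.X.T @ sd.y)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-8)

    def test_orthonormal_soft_threshold_closed_form(self):
        """On orthonormal columns the solution is exactly the soft threshold
        of x_j'y at lam/2."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            A = rng.standard_normal((20, 3))
            Q, _ = np.linalg.qr(A)
            y = rng.standard_normal(20)
            lam = float(rng.uniform(0.1, 2.0))
            sd = sdesign(Q, y)
            fit = cv.fit_lasso(sd, lam)
            z = Q.T @ y
            expected = np.sign(z) * np.maximum(np.abs(z) - lam / 2, 0.0)
            np.testing.assert_allclose(fit.beta, expected, atol=1e-8)

    def test_kkt_stationarity(self):
        """|2 x_j'(y - Xb)| <= lam off the support; equality with matching
        sign on the support."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            sd = std_random(rng, int(rng.integers(8, 25)), 3)
            lam = float(rng.uniform(0.0, 1.2)) * max(cv.lambda_max(sd), 1e-6)
            fit = cv.fit_lasso(sd, lam)
            grad = 2.0 * sd.X.T @ (sd.y - sd.X @ fit.beta)
            for j, name in enumerate(sd.column_names):
                if name in fit.support:
                    assert grad[j] == pytest.approx(lam * np.sign(fit.beta[j]),
                                                    abs=1e-6)
                else:
                    assert abs(grad[j]) <= lam + 1e-6

    def test_objective_beats_perturbations_and_restricted_refits(self):
        """The solver's penalised objective is a global minimum: no random
        perturbation nor any support-restricted shrunken refit does better."""
        rng = np.random.default_rng(17)

        def objective(sd, b, lam):
            r = sd.y - sd.X @ b
            return r @ r + lam * np.abs(b).sum()

        for _ in range(5):
            sd = std_random(rng, 15, 3)
            lam = 0.4 * cv.lambda_max(sd)
            fit = cv.fit_lasso(sd, lam)
            best = objective(sd, fit.beta, lam)
            # 10^4 random perturbations around the solution
            pert = fit.beta + rng.standard_normal((10_000, 3)) * 0.3
            vals = (np.sum((sd.y[:, None] - sd.X @ pert.T) ** 2, axis=0)
                    + lam * np.abs(pert).sum(axis=1))
            assert best <= vals.min() + 1e-9
            # all 8 supports: OLS refit then a shrinkage grid on each coord
            for mask in range(8):
                idx = [j for j in range(3) if mask >> j & 1]
                if not idx:
                    assert best <= objective(sd, np.zeros(3), lam) + 1e-9
                    continue
                Xa = sd.X[:, idx]
                bo = np.linalg.solve(Xa.T @ Xa, Xa.T @ sd.y)
                for scale in np.linspace(0.0, 1.2, 25):
                    b = np.zeros(3)
                    b[idx] = bo * scale
                    assert best <= objective(sd, b, lam) + 1e-9

    def test_negative_lambda_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(cv.ValidationError):
            cv.fit_lasso(std_random(rng, 10, 2), -1.0)


class TestLassoPath:
    def test_grid_shape_and_first_fit_empty(self):
        rng = np.random.default_rng(23)
        sd = std_random(rng, 18, 3)
        path = cv.lasso_path(sd, n_lambda=30)
        assert len(path.fits) == 30
        assert np.all(np.diff(path.lambdas) < 0)
        assert path.fits[0].support == frozenset()

    def test_path_end_near_ols(self):
        rng = np.random.default_rng(29)
        sd = std_random(rng, 40, 3)
        path = cv.lasso_path(sd, n_lambda=100, eps=1e-3)
        beta = np.linalg.solve(sd.X.T @ sd.X, sd.X.T @ sd.y)
        np.testing.assert_allclose(path.fits[-1].beta, beta, rtol=1e-2, atol=1e-3)

    def test_support_monotone_on_orthogonal_design(self):
        rng = np.random.default_rng(31)
        A = rng.standard_normal((24, 3))
        Q, _ = np.linalg.qr(A)
        sd = sdesign(Q, rng.standard_normal(24))
        path = cv.lasso_path(sd, n_lambda=40)
        sizes = [len(f.support) for f in path.fits]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))


class TestSigma2AndBic:
    def test_alternating_residuals_example(self):
        """Residuals (+1, -1, +1, -1) around group means with p = 1, n = 4
        give RSS/(n-p-1) = 4/2 = 2."""
        d = cv.DesignMatrix(model_form="simple",
                            X=np.array([[0.0], [0.0], [1.0], [1.0]]),
                            y=np.array([3.0, 1.0, 6.0, 4.0]),
                            coding={}, column_names=("X1",))
        assert cv.estimate_sigma2(d) == pytest.approx(2.0)

    def test_noiseless_sigma2_zero(self):
        d = cv.DesignMatrix(model_form="simple",
                            X=np.arange(6, dtype=float)[:, None],
                            y=2.0 + 3.0 * np.arange(6),
                            coding={}, column_names=("X1",))
        assert cv.estimate_sigma2(d) == pytest.approx(0.0, abs=1e-18)

    def test_sigma2_consistency_large_n(self):
        rng = np.random.default_rng(37)
        n = 10_000
        X = rng.integers(0, 2, size=(n, 2)).astype(float)
        X = np.column_stack([X, X[:, 0] * X[:, 1]])
        y = 4 + X @ [1.0, -0.5, 0.7] + 0.3 * rng.standard_normal(n)
        d = cv.DesignMatrix(model_form="interaction", X=X, y=y, coding={},
                            column_names=("X1", "X2", "X1X2"))
        assert cv.estimate_sigma2(d) == pytest.approx(0.09, rel=0.05)

    def _fake_path(self, entries, n):
        # entries: list of (rss, support_names)
        fits = tuple(
            LassoFit(lam=float(len(entries) - k), beta=np.zeros(3),
                     beta_original=np.zeros(3), intercept=0.0,
                     support=frozenset(sup), rss=rss,
                     column_names=("X1", "X2", "X1X2"))
            for k, (rss, sup) in enumerate(entries))
        return LassoPath(np.arange(len(entries), 0, -1, dtype=float), fits, n)

    def test_bic_arithmetic(self):
        path = self._fake_path([(5.0, ("X1", "X2"))], n=10)
        sel = cv.select_by_bic(path, 1.0)
        assert sel.bic_values[0] == pytest.approx((5 + np.log(10) * 2) / 10)
        assert sel.bic_values[0] == pytest.approx(0.96052, abs=1e-5)

    def test_bic_no_penalty_for_intercept_only(self):
        path = self._fake_path([(5.0, ())], n=10)
        sel = cv.select_by_bic(path, 1.0)
        assert sel.bic_values[0] == pytest.approx(0.5)

    def test_equal_rss_prefers_smaller_support(self):
        path = self._fake_path([(5.0, ("X1",)), (5.0, ("X1", "X2"))], n=10)
        sel = cv.select_by_bic(path, 1.0)
        assert sel.chosen.support == frozenset({"X1"})

    def test_tie_goes_to_larger_lambda(self):
        path = self._fake_path([(5.0, ("X1",)), (5.0, ("X2",))], n=10)
        sel = cv.select_by_bic(path, 1.0)
        assert sel.chosen.lam == 2.0  # first grid point

    def test_noiseless_selection_recovers_true_support(self):
        """With sigma2 = 0 the BIC penalty vanishes and RSS alone picks the
        path end; on noiseless data the true predictors survive."""
        rng = np.random.default_rng(41)
        X = rng.integers(0, 2, size=(24, 2)).astype(float)
        X = np.column_stack([X, X[:, 0] * X[:, 1]])
        while np.ptp(X[:, 2]) == 0:
            X = rng.integers(0, 2, size=(24, 2)).astype(float)
            X = np.column_stack([X, X[:, 0] * X[:, 1]])
        y = 4 + X @ [1.0, 0.0, 0.8]
        d = cv.DesignMatrix(model_form="interaction", X=X, y=y, coding={},
                            column_names=("X1", "X2", "X1X2"))
        sd = cv.standardize(d)
        sel = cv.select_by_bic(cv.lasso_path(sd), cv.estimate_sigma2(d), sd=sd)
        assert {"X1", "X1X2"} <= set(sel.chosen.support)
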
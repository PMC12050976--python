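import warnings

import numpy as np
import pytest
from scipy.stats import norm

from ziqsir import (
    Dataset,
    DGPConfig,
    FitConfig,
    check_loss,
    fit_null,
    fit_theta,
    predict_G,
    profile_loss,
)
from ziqsir.single_index import _qreg_irls, pseudo_likelihood
from ziqsir.splines import SplineBasis, build_basis, eval_basis

from .conftest import FAST_FIT


class TestCheckLoss:
    @pytest.mark.parametrize(
        ("u", "tau", "expected"),
        [(0.0, 0.3, 0.0), (2.0, 0.25, 0.5), (-2.0, 0.25, 1.5), (1.0, 0.9, 0.9)],
    )
    def test_values(self, u, tau, expected):
        assert check_loss(u, tau) == pytest.approx(expected)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            check_loss(1.0, 1.5)

    def test_nonnegative_piecewise_linear(self):
        u = np.linspace(-3, 3, 101)
        loss = check_loss(u, 0.4)
        assert np.all(loss >= 0)
        slopes = np.diff(loss) / np.diff(u)
        assert set(np.round(slopes, 10)) <= {0.4, -0.6}


class TestFitTheta:
    def test_single_span_constant_is_sample_quantile(self, rng):
        """An order-1 single-span basis fits the empirical tau-quantile of
        the positive responses (any minimizer lies between adjacent order
        statistics and attains the same loss)."""
        n = 201
        Y = np.concatenate([np.zeros(50), rng.gamma(2.0, 2.0, n - 50) + 0.1])
        data = Dataset(Y=Y, Z=np.zeros((n, 0)), C=rng.standard_normal((n, 1)))
        basis = SplineBasis(order=1, boundary=(-5.0, 5.0))
        for tau in (0.25, 0.5, 0.9):
            theta = fit_theta(data, None, np.ones(1), tau, basis)
            ypos = np.sort(Y[Y > 0])
            oracle = np.quantile(ypos, tau)
            loss_fit = check_loss(ypos - theta[0], tau).sum()
            loss_oracle = check_loss(ypos - oracle, tau).sum()
            assert loss_fit <= loss_oracle * (1 + 1e-6) + 1e-9

    def test_perfect_spline_data_zero_loss(self, rng):
        n = 300
        C = rng.uniform(0, 1, (n, 1))
        u = C[:, 0]
        basis = build_basis(u, 2, order=4)
        theta0 = np.abs(rng.standard_normal(basis.dimension)) + 1.0
        Y = eval_basis(basis, u) @ theta0
        data = Dataset(Y=Y, Z=np.zeros((n, 0)), C=C)
        theta = fit_theta(data, None, np.ones(1), 0.5, basis)
        loss = pseudo_likelihood(data, None, np.ones(1), theta, 0.5, basis)
        assert loss < 1e-6

    def test_permutation_invariance(self, rng):
        n = 150
        C = rng.standard_normal((n, 1))
        Y = np.abs(rng.standard_normal(n))
        Y[:30] = 0.0
        basis = build_basis(C[Y > 0, 0], 1, order=4)
        d1 = Dataset(Y=Y, Z=np.zeros((n, 0)), C=C)
        perm = rng.permutation(n)
        d2 = Dataset(Y=Y[perm], Z=np.zeros((n, 0)), C=C[perm])
        t1 = fit_theta(d1, None, np.ones(1), 0.3, basis)
        t2 = fit_theta(d2, None, np.ones(1), 0.3, basis)
        np.testing.assert_allclose(t1, t2, atol=1e-8)


class TestProfileLoss:
    def test_profile_is_inner_minimum(self, rng):
        """Profile loss lower-bounds the loss at random theta draws."""
        n = 250
        C = rng.standard_normal((n, 2))
        Y = np.abs(C @ [1.0, 0.5]) + rng.random(n)
        Y[:40] = 0.0
        data = Dataset(Y=Y, Z=np.zeros((n, 0)), C=C)
        beta = np.array([0.8, 0.6])
        cfg = FitConfig()
        prof = profile_loss(data, None, beta, 0.5, cfg)
        u = (data.C @ beta)[data.D]
        basis = build_basis(u, max(1, round(data.n_positive ** 0.2)), 4)
        for _ in range(100):
            theta = rng.standard_normal(basis.dimension) * 3
            assert prof <= pseudo_likelihood(data, None, beta, theta, 0.5, basis) + 1e-9

    def test_beta_rescaling_absorbed_by_link(self, rng):
        """Scaling beta rescales the index, which the refit basis absorbs."""
        n = 300
        C = rng.standard_normal((n, 2))
        Y = np.abs(C @ [1.0, -0.5]) + rng.random(n)
        Y[:50] = 0.0
        data = Dataset(Y=Y, Z=np.zeros((n, 0)), C=C)
        beta = np.array([0.6, 0.8])
        l1 = profile_loss(data, None, beta, 0.4)
        l2 = profile_loss(data, None, 2.0 * beta, 0.4)
        assert l1 == pytest.approx(l2, rel=1e-6)


class TestFitNull:
    def test_q1_closed_case(self, rng):
        n = 200
        C = rng.uniform(0.5, 2.0, (n, 1))
        Y = C[:, 0] ** 2 + rng.random(n)
        Y[:20] = 0.0
        data = Dataset(Y=Y, Z=np.zeros((n, 0)), C=C)
        fit = fit_null(data, 0.5)
        np.testing.assert_allclose(fit.beta_hat, [1.0])
        assert fit.converged

    def test_unit_norm_and_sign_convention(self, null_fit_500):
        assert np.linalg.norm(null_fit_500.beta_hat) == pytest.approx(1.0, abs=1e-8)
        nz = null_fit_500.beta_hat[np.abs(null_fit_500.beta_hat) > 1e-12]
        assert nz[0] > 0

    def test_loss_matches_pseudo_likelihood(self, alt_dataset_500, null_fit_500):
        loss = pseudo_likelihood(
            alt_dataset_500, None, null_fit_500.beta_hat,
            null_fit_500.theta_hat, 0.5, null_fit_500.basis,
        )
        assert loss == pytest.approx(null_fit_500.loss, abs=1e-10)

    def test_parameter_recovery_cubic_link(self):
        """Y|Y>0 = (C'b)^3 + Gaussian quantile noise recovers b = (0.6, 0.8)."""
        beta0 = np.array([0.6, 0.8])
        errs = []
        for rep in range(8):
            rng = np.random.default_rng(500 + rep)
            n = 2000
            C = rng.standard_normal((n, 2))
            tau_i = rng.uniform(0, 1, n)
            Y = (C @ beta0) ** 3 + norm.ppf(tau_i)
            keep = Y > 0
            data = Dataset(Y=np.where(keep, Y, 0.0), Z=np.zeros((n, 0)), C=C)
            fit = fit_null(data, 0.5, FitConfig(seed=rep))
            errs.append(np.linalg.norm(fit.beta_hat - beta0))
        assert np.median(errs) < 0.1

    def test_identity_link_matches_linear_quantile_regression(self):
        """With a linear truth the direction matches statsmodels QuantReg."""
        import statsmodels.api as sm

        rng = np.random.default_rng(77)
        n = 2000
        C = rng.standard_normal((n, 3))
        beta0 = np.array([2.0, -1.0, 0.5])
        Y = 10.0 + C @ beta0 + rng.standard_normal(n)
        data = Dataset(Y=np.maximum(Y, 0), Z=np.zeros((n, 0)), C=C)
        fit = fit_null(data, 0.5, FAST_FIT)
        X = sm.add_constant(C[data.D])
        qr = sm.QuantReg(data.Y[data.D], X).fit(q=0.5)
        direction = qr.params[1:] / np.linalg.norm(qr.params[1:])
        agree = abs(float(direction @ fit.beta_hat))
        assert agree > 0.98

    def test_identity_link_fitted_G_is_affine(self):
        rng = np.random.default_rng(99)
        n = 2000
        C = rng.standard_normal((n, 2))
        Y = 5.0 + C @ [1.5, -1.0] + rng.standard_normal(n)
        data = Dataset(Y=np.maximum(Y, 0), Z=np.zeros((n, 0)), C=C)
        fit = fit_null(data, 0.5, FAST_FIT)
        u = np.linspace(*fit.basis.boundary, 200)
        G, _ = predict_G(fit, u)
        r = np.corrcoef(u, G)[0, 1] ** 2
        assert r > 0.99

    def test_fit_ignores_zero_rows(self, rng):
        """Perturbing the response on zero rows cannot change the fit."""
        n = 400
        C = rng.standard_normal((n, 2))
        Y = np.abs(C @ [1.0, 1.0]) + rng.random(n)
        Y[:100] = 0.0
        d1 = Dataset(Y=Y, Z=np.zeros((n, 0)), C=C)
        fit1 = fit_null(d1, 0.5, FAST_FIT)
        # zero rows stay zero-coded; only covariates there change
        C2 = C.copy()
        C2[:100] += rng.standard_normal((100, 2)) * 10
        fit2 = fit_null(Dataset(Y=Y, Z=np.zeros((n, 0)), C=C2), 0.5, FAST_FIT)
        np.testing.assert_array_equal(fit1.beta_hat, fit2.beta_hat)
        np.testing.assert_array_equal(fit1.theta_hat, fit2.theta_hat)

    def test_too_few_positives_raises(self, rng):
        Y = np.concatenate([np.zeros(95), np.ones(5)])
        data = Dataset(Y=Y, Z=np.zeros((100, 0)), C=rng.standard_normal((100, 2)))
        with pytest.raises(ValueError):
            fit_null(data, 0.5)


class TestPredictG:
    def test_zero_theta_gives_zero_link(self, null_fit_500):
        from dataclasses import replace

        fit = replace(null_fit_500, theta_hat=np.zeros_like(null_fit_500.theta_hat))
        G, G1 = predict_G(fit, np.linspace(-1, 1, 10))
        np.testing.assert_array_equal(G, 0.0)
        np.testing.assert_array_equal(G1, 0.0)

    def test_constant_theta_gives_constant_link(self, null_fit_500):
        from dataclasses import replace

        fit = replace(null_fit_500, theta_hat=np.full(null_fit_500.basis.dimension, 3.5))
        a, b = fit.basis.boundary
        G, G1 = predict_G(fit, np.linspace(a, b, 20))
        np.testing.assert_allclose(G, 3.5, atol=1e-10)
        np.testing.assert_allclose(G1, 0.0, atol=1e-10)

    def test_derivative_matches_finite_difference(self, null_fit_500):
        a, b = null_fit_500.basis.boundary
        u = np.linspace(a + 0.05 * (b - a), b - 0.05 * (b - a), 25)
        h = 1e-6 * (b - a)
        Gp, _ = predict_G(null_fit_500, u + h)
        Gm, _ = predict_G(null_fit_500, u - h)
        _, G1 = predict_G(null_fit_500, u)
        np.testing.assert_allclose((Gp - Gm) / (2 * h), G1, rtol=1e-3, atol=1e-5)


class TestQregIrls:
    def test_agrees_with_statsmodels_quantreg(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 500
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        y = X @ [1.0, 2.0, -1.0, 0.5] + rng.standard_normal(n) * 0.7
        for tau in (0.25, 0.5, 0.75):
            beta, loss = _qreg_irls(X, y, tau)
            sm_fit = sm.QuantReg(y, X).fit(q=tau)
            loss_sm = float(check_loss(y - X @ sm_fit.params, tau).mean())
            # same objective value as the reference solver
            assert loss == pytest.approx(loss_sm, rel=5e-3, abs=1e-4)
            np.testing.assert_allclose(beta, sm_fit.params, atol=0.05)
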
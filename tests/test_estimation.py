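import numpy as np
import pytest
from scipy.optimize import minimize

from fourierlogit import (
    CoefficientSet,
    DimensionError,
    OscillationCombo,
    SeparationError,
    SeparationWarning,
    SyntheticSpec,
    ValidationError,
    aic_of,
    build_design,
    deviance_of,
    fit_binary_logistic,
    fit_fourier_logit,
    generate_dataset,
    hessian_matrix,
    inverse_logit,
    linear_predictor,
    log_likelihood,
    newton_raphson_fit,
    score_vector,
)


def finite_diff_grad(f, x, h=1e-6):
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


class TestCoefficientSet:
    def test_flat_round_trip(self, rng):
        combo = OscillationCombo((2, 0, 3))
        flat = rng.normal(size=combo.n_params())
        cs = CoefficientSet.from_flat(flat, combo)
        np.testing.assert_array_equal(cs.to_flat(), flat)
        assert cs.combo.ks == combo.ks

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            CoefficientSet.from_flat(np.zeros(3), OscillationCombo((2, 1)))


class TestLogLikelihood:
    def test_zero_beta_gives_n_log_half(self, small_problem):
        Z, _ = small_problem
        y = np.array([0, 1] * 10)[: Z.n]
        ll = log_likelihood(np.zeros(Z.m), Z, y[: Z.n])
        assert ll == pytest.approx(Z.n * np.log(0.5))

    def test_saturating_contribution_vanishes(self):
        Z = build_design(np.array([[1.0]]), (0,))
        # large positive eta with y=1: contribution ~ 0
        ll = log_likelihood(np.array([0.0, 40.0]), Z, np.array([1]))
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_matches_pmf_product(self, rng):
        Z = build_design(rng.uniform(0, 6, size=(20, 2)), (1, 1))
        beta = rng.normal(scale=0.5, size=Z.m)
        y = rng.binomial(1, 0.5, size=20)
        pi = inverse_logit(linear_predictor(Z, beta))
        oracle = float(np.sum(np.log(np.where(y == 1, pi, 1 - pi))))
        assert log_likelihood(beta, Z, y) == pytest.approx(oracle, rel=1e-10)

    def test_bad_response_coding(self, small_problem):
        Z, y = small_problem
        bad = y.copy()
        bad[0] = 2
        with pytest.raises(ValidationError):
            log_likelihood(np.zeros(Z.m), Z, bad)


class TestScoreVector:
    def test_intercept_only_zero_at_mean(self):
        # pi = mean(y) solves the half-intercept score equation
        Z = build_design(np.zeros((8, 1)), (0,))
        Zi = Z.Z[:, :1]  # intercept-only design
        y = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        a0 = 2 * np.log(np.mean(y) / (1 - np.mean(y)))
        g = Zi.T @ (y - inverse_logit(Zi @ np.array([a0])))
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_balanced_symmetric_design(self):
        x = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        Z = build_design(x, (0,))
        # residuals y - 1/2 antisymmetric in x: linear-term score cancels
        y = np.array([1, 0, 0, 1])
        g = score_vector(np.zeros(2), Z, y)
        assert g[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_finite_differences(self, rng):
        Z = build_design(rng.uniform(0, 6, size=(20, 2)), (1, 1))
        y = rng.binomial(1, 0.5, size=20)
        beta = rng.normal(scale=0.3, size=Z.m)
        g = score_vector(beta, Z, y)
        fd = finite_diff_grad(lambda b: log_likelihood(b, Z, y), beta)
        np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-7)


class TestHessian:
    def test_intercept_entry_at_zero_beta(self, small_problem):
        Z, _ = small_problem
        H = hessian_matrix(np.zeros(Z.m), Z)
        # half-column squared times pi(1-pi)=1/4: -n/16
        assert H[0, 0] == pytest.approx(-Z.n / 16.0)

    def test_symmetric_negative_semidefinite(self, rng):
        Z = build_design(rng.uniform(0, 6, size=(15, 2)), (2, 1))
        beta = rng.normal(size=Z.m)
        H = hessian_matrix(beta, Z)
        np.testing.assert_allclose(H, H.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(H) <= 1e-10)

    def test_matches_finite_differences_of_score(self, rng):
        Z = build_design(rng.uniform(0, 6, size=(20, 2)), (1, 1))
        y = rng.binomial(1, 0.5, size=20)
        beta = rng.normal(scale=0.3, size=Z.m)
        H = hessian_matrix(beta, Z)
        h = 1e-6
        for i in range(Z.m):
            e = np.zeros(Z.m)
            e[i] = h
            col = (score_vector(beta + e, Z, y) - score_vector(beta - e, Z, y)) / (2 * h)
            np.testing.assert_allclose(H[:, i], col, rtol=1e-4, atol=1e-6)


class TestNewtonRaphson:
    def test_intercept_only_balanced(self):
        Z = build_design(np.zeros((10, 1)), (0,))
        Zi = Z.Z[:, :1]
        y = np.array([0, 1] * 5)
        fit = newton_raphson_fit(Zi, y)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_three_quarters(self):
        # mean(y)=0.75 => a0 = 2 logit(0.75) = 2 ln 3
        Zi = np.full((8, 1), 0.5)
        y = np.array([1, 1, 1, 0] * 2)
        fit = newton_raphson_fit(Zi, y)
        assert fit.beta[0] == pytest.approx(2 * np.log(3.0), abs=1e-6)

    def test_matches_generic_quasi_newton(self):
        spec = SyntheticSpec(
            n=500,
            true_combo=OscillationCombo((2, 1)),
            true_beta=CoefficientSet(
                0.4, np.array([0.2, -0.1]), (np.array([1.5, -1.0]), np.array([1.2]))
            ),
            seed=1,
        )
        ds = generate_dataset(spec)
        Z = build_design(ds.X, spec.true_combo)
        fit = newton_raphson_fit(Z, ds.y)
        assert fit.converged

        def neg_ll(b):
            return -log_likelihood(b, Z, ds.y)

        def neg_grad(b):
            return -score_vector(b, Z, ds.y)

        res = minimize(neg_ll, np.zeros(Z.m), jac=neg_grad, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        np.testing.assert_allclose(fit.beta, res.x, atol=1e-6)

    def test_monotone_loglik_trace(self, cosine_dataset):
        Z = build_design(cosine_dataset.X, cosine_dataset.spec.true_combo)
        fit = newton_raphson_fit(Z, cosine_dataset.y)
        lls = [ll for ll, _ in fit.trace]
        assert all(b >= a - 1e-12 for a, b in zip(lls, lls[1:]))

    def test_score_small_at_optimum(self, cosine_dataset):
        fit = fit_fourier_logit(cosine_dataset.X, cosine_dataset.y, (2, 1))
        assert fit.converged
        assert fit.grad_maxnorm < 1e-5

    def test_single_class_raises(self):
        Zi = np.full((6, 1), 0.5)
        with pytest.raises(SeparationError):
            newton_raphson_fit(Zi, np.ones(6, dtype=int))

    def test_fit_result_identities(self, cosine_dataset):
        fit = fit_fourier_logit(cosine_dataset.X, cosine_dataset.y, (2, 1))
        assert deviance_of(fit) == pytest.approx(-2 * fit.loglik)
        assert aic_of(fit) == pytest.approx(fit.deviance + 2 * fit.m)
        assert fit.m == 1 + 2 + 3

    def test_structured_coefficients(self, cosine_dataset):
        fit = fit_fourier_logit(cosine_dataset.X, cosine_dataset.y, (2, 1))
        cs = fit.beta_hat
        assert cs.combo.ks == (2, 1)
        np.testing.assert_array_equal(cs.to_flat(), fit.beta)


class TestBinaryLogistic:
    def test_balanced_symmetric_beta0_near_zero(self):
        y = np.array([0, 1] * 5)
        fit = fit_binary_logistic(np.linspace(-1, 1, 10).reshape(-1, 1), y)
        assert fit.converged
        assert abs(fit.beta[0]) < 0.7

    def test_matches_statsmodels_irls(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(1000, 3))
        eta = 0.5 + X @ np.array([1.0, -0.7, 0.3])
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        fit = fit_binary_logistic(X, y)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        assert fit.deviance == pytest.approx(ref.deviance, rel=1e-8)

    def test_perfect_separation_flagged(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.warns((SeparationWarning, UserWarning)):
            fit = fit_binary_logistic(X, y)
        assert not fit.converged
        assert any("separation" in w for w in fit.warnings_)

    def test_zero_combo_fourier_equals_logistic(self, linear_dataset):
        X, y = linear_dataset.X, linear_dataset.y
        ffit = fit_fourier_logit(X, y, (0, 0))
        lfit = fit_binary_logistic(X, y)
        # a0 = 2 beta0, b_j = beta_j
        assert ffit.beta[0] == pytest.approx(2 * lfit.beta[0], abs=1e-6)
        np.testing.assert_allclose(ffit.beta[1:], lfit.beta[1:], atol=1e-6)
        assert ffit.loglik == pytest.approx(lfit.loglik, abs=1e-9)


class TestDevianceClosedForms:
    def test_null_half_model(self):
        Zi = np.full((12, 1), 0.5)
        y = np.array([0, 1] * 6)
        fit = newton_raphson_fit(Zi, y)
        assert fit.deviance == pytest.approx(2 * 12 * np.log(2.0), rel=1e-9)

    def test_printed_aic_identity_case2(self):
        # deviance 24.0027 with combo (4,3,4) over p=3: m = 1+3+11 = 15
        combo = OscillationCombo((4, 3, 4))
        assert combo.n_params() == 15
        assert 24.0027 + 2 * combo.n_params() == pytest.approx(54.0027)

    def test_printed_aic_identity_case1(self):
        combo = OscillationCombo((3, 2, 1, 1, 1, 1))
        assert combo.n_params() == 16
        assert 136.4056 + 2 * combo.n_params() == pytest.approx(168.4055, abs=2e-4)


class TestParameterRecovery:
    @pytest.mark.parametrize("n_small,n_large", [(500, 5000)])
    def test_rmse_decreases_with_n(self, n_small, n_large):
        combo = OscillationCombo((2, 1))
        truth = CoefficientSet(
            0.5, np.array([0.3, -0.2]), (np.array([2.0, -1.5]), np.array([1.8]))
        )
        flat_true = truth.to_flat()

        def rmse(n, seed):
            ds = generate_dataset(
                SyntheticSpec(n=n, true_combo=combo, true_beta=truth, seed=seed)
            )
            fit = fit_fourier_logit(ds.X, ds.y, combo)
            return np.sqrt(np.mean((fit.beta - flat_true) ** 2))

        small = np.mean([rmse(n_small, s) for s in range(5)])
        large = np.mean([rmse(n_large, s) for s in range(5)])
        assert large < small
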
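"""ML and Firth fitters, Wald and profile penalized-likelihood intervals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2

from epvsim.datagen import Dataset, SamplingSpec, TrueModel, sample_quota
from epvsim.estimators import (
    CONVERGENCE_PRESETS,
    ConvergenceSpec,
    InvalidOutcomeError,
    SingularDesignError,
    fit_firth,
    fit_ml,
    profile_ci,
    wald_ci,
)

STRICT = ConvergenceSpec(1e-12, 200)


def table_2x2(e1, e0, ne1, ne0) -> Dataset:
    """events at x=1, events at x=0, non-events at x=1, non-events at x=0."""
    x = np.concatenate([np.ones(e1), np.zeros(e0), np.ones(ne1), np.zeros(ne0)])
    y = np.concatenate([np.ones(e1 + e0, dtype=int), np.zeros(ne1 + ne0, dtype=int)])
    return Dataset(X=x[:, None], y=y)


def penalized_loglik_oracle(X, y, beta):
    """Independent Jeffreys-penalized log-likelihood, written from scratch."""
    Z = np.column_stack([np.ones(len(y)), X])
    eta = Z @ np.asarray(beta)
    pi = expit(eta)
    ll = np.sum(y * np.log(pi) + (1 - y) * np.log1p(-pi))
    W = pi * (1 - pi)
    info = (Z * W[:, None]).T @ Z
    return ll + 0.5 * np.linalg.slogdet(info)[1]


class TestMaximumLikelihood:
    def test_symmetric_table_gives_zero(self, toys):
        fit = fit_ml(toys["cells_5555"], STRICT)
        np.testing.assert_allclose(fit.coefficients, [0.0, 0.0], atol=1e-9)

    def test_2x2_closed_form(self, toys):
        """beta1 = log OR of the table; SE = sqrt of summed 1/counts."""
        fit = fit_ml(toys["cells_6446"], STRICT)
        assert fit.coefficients[1] == pytest.approx(np.log(2.25), abs=1e-8)
        assert fit.standard_errors[1] == pytest.approx(
            np.sqrt(1 / 6 + 1 / 4 + 1 / 4 + 1 / 6), abs=1e-6
        )
        assert fit.converged

    def test_matches_statsmodels(self, toys):
        sm = pytest.importorskip("statsmodels.api")
        data = toys["overlapped_200"]
        X = sm.add_constant(data.X)
        ref = sm.Logit(data.y, X).fit(disp=0)
        ours = fit_ml(data, STRICT)
        np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.standard_errors, ref.bse, atol=1e-5)

    def test_divergence_on_separated_data(self, toys):
        """No finite MLE exists: estimates grow with the iteration cap."""
        data = toys["complete_sep"]
        estimates = [
            fit_ml(data, ConvergenceSpec(1e-300, cap)).coefficients[1]
            for cap in (10, 25, 50)
        ]
        assert estimates[0] > 5
        assert estimates[0] < estimates[1] < estimates[2]

    def test_expected_info_se_matches_finite_difference_hessian(self, toys):
        """At the optimum, expected and observed information coincide."""
        data = toys["overlapped_200"]
        fit = fit_ml(data, STRICT)
        Z = np.column_stack([np.ones(data.n), data.X])

        def nll(b):
            eta = Z @ b
            return -(data.y @ eta - np.logaddexp(0, eta).sum())

        k = len(fit.coefficients)
        h = 1e-5
        H = np.empty((k, k))
        for i in range(k):
            for j in range(k):
                b = fit.coefficients.copy()
                ei = np.eye(k)[i] * h
                ej = np.eye(k)[j] * h
                H[i, j] = (nll(b + ei + ej) - nll(b + ei - ej)
                           - nll(b - ei + ej) + nll(b - ei - ej)) / (4 * h * h)
        se_fd = np.sqrt(np.diag(np.linalg.inv(H)))
        np.testing.assert_allclose(fit.standard_errors, se_fd, atol=1e-4)

    def test_error_on_single_class_and_rank_deficiency(self):
        with pytest.raises(InvalidOutcomeError):
            fit_ml(Dataset(X=np.array([[1.0], [2.0]]), y=np.array([1, 1])))
        with pytest.raises(SingularDesignError):
            fit_ml(Dataset(X=np.ones((6, 1)), y=np.array([0, 1, 0, 1, 0, 1])))


class TestFirth:
    def test_symmetric_table_gives_zero(self, toys):
        fit = fit_firth(toys["cells_5555"], STRICT)
        np.testing.assert_allclose(fit.coefficients, [0.0, 0.0], atol=1e-8)

    def test_2x2_equals_add_half_correction(self, toys):
        """Single binary covariate: Firth = log OR after adding 1/2 per cell."""
        fit = fit_firth(toys["cells_6446"], STRICT)
        expected = np.log((6.5 * 6.5) / (4.5 * 4.5))
        assert fit.coefficients[1] == pytest.approx(expected, abs=1e-6)

    def test_finite_on_separated_data_and_matches_numeric_optimum(self, toys):
        """Penalized MLE on separated data is finite; cross-checked against
        direct numerical maximization of an independently coded l*."""
        data = toys["complete_sep"]
        fit = fit_firth(data, STRICT)
        assert np.all(np.isfinite(fit.coefficients))
        assert np.all(fit.standard_errors > 0)
        res = minimize(
            lambda b: -penalized_loglik_oracle(data.X, data.y, b),
            x0=np.zeros(2),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        np.testing.assert_allclose(fit.coefficients, res.x, atol=1e-4)

    def test_penalized_deviance_nonincreasing(self, toys):
        """Step-halving guarantees ascent of the penalized likelihood."""
        for name in ("cells_6446", "complete_sep", "overlapped_200"):
            trace = fit_firth(toys[name]).deviance_trace
            assert np.all(np.diff(trace) <= 1e-10)

    def test_agrees_with_ml_at_large_n(self):
        model = TrueModel(0.0, (np.log(2.0),), "normal")
        data = sample_quota(model, SamplingSpec(5000, 2500, 77))
        d = np.abs(fit_firth(data, STRICT).coefficients - fit_ml(data, STRICT).coefficients)
        assert np.all(d < 0.01)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(1, 8), st.integers(1, 8), st.integers(1, 8), st.integers(1, 8))
def test_firth_shrinks_single_binary_covariate(e1, e0, ne1, ne0):
    """|Firth slope| <= |ML slope| whenever the table MLE is finite."""
    data = table_2x2(e1, e0, ne1, ne0)
    ml = fit_ml(data, STRICT)
    fr = fit_firth(data, STRICT)
    assert abs(fr.coefficients[1]) <= abs(ml.coefficients[1]) + 1e-6


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_outcome_recoding_antisymmetry(seed):
    """Recoding y -> 1-y flips the sign of every coefficient, both methods."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 24))
    p = int(rng.integers(1, 3))
    X = rng.standard_normal((n, p))
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    rng.shuffle(y)
    data = Dataset(X=X, y=y)
    flipped = Dataset(X=X, y=1 - y)
    for fitter in (fit_ml, fit_firth):
        a = fitter(data).coefficients
        b = fitter(flipped).coefficients
        np.testing.assert_allclose(a, -b, atol=1e-6)


class TestWaldInterval:
    def test_unit_se_at_90(self):
        fit = fit_ml(table_2x2(5, 5, 5, 5))
        fit.coefficients = np.array([0.0, 0.0])
        fit.standard_errors = np.array([1.0, 1.0])
        ci = wald_ci(fit, 1, 0.90)
        assert ci.lower == pytest.approx(-1.6449, abs=5e-4)
        assert ci.upper == pytest.approx(1.6449, abs=5e-4)
        assert ci.width == pytest.approx(3.29, abs=1e-3)

    def test_95_level(self):
        fit = fit_ml(table_2x2(5, 5, 5, 5))
        fit.coefficients = np.array([0.0, 0.0])
        fit.standard_errors = np.array([1.0, 1.0])
        ci = wald_ci(fit, 1, 0.95)
        assert ci.lower == pytest.approx(-1.960, abs=1e-3)

    def test_2x2_interval(self, toys):
        fit = fit_ml(toys["cells_6446"], STRICT)
        ci = wald_ci(fit, 1, 0.90)
        assert ci.lower == pytest.approx(-0.691, abs=2e-3)
        assert ci.upper == pytest.approx(2.313, abs=2e-3)


class TestProfileInterval:
    def profiled_pl_oracle(self, data, b1):
        """1-D inner maximization over the intercept, independent code."""
        res = minimize(
            lambda b0: -penalized_loglik_oracle(data.X, data.y, [b0[0], b1]),
            x0=np.zeros(1),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-13},
        )
        return -res.fun

    @pytest.mark.parametrize("name", ["cells_6446", "complete_sep"])
    def test_endpoints_satisfy_defining_equation(self, toys, name):
        """Twice the profiled penalized-likelihood drop at either endpoint
        equals the chi-square 90% quantile (2.706)."""
        data = toys[name]
        fit = fit_firth(data, STRICT)
        ci = profile_ci(data, fit, 1, 0.90)
        assert ci.lower < fit.coefficients[1] < ci.upper
        for endpoint in (ci.lower, ci.upper):
            drop = 2 * (fit.loglik - self.profiled_pl_oracle(data, endpoint))
            assert drop == pytest.approx(chi2.ppf(0.90, 1), abs=1e-3)

    def test_matches_grid_profile_oracle(self, toys):
        """Endpoints agree with a dense grid over beta1 with 1-D inner
        maximization over the intercept."""
        data = toys["cells_6446"]
        fit = fit_firth(data, STRICT)
        target = fit.loglik - 0.5 * chi2.ppf(0.90, 1)
        grid = np.linspace(-2.0, 3.5, 1101)
        pl = np.array([self.profiled_pl_oracle(data, b) for b in grid])
        above = grid[pl >= target]
        ci = profile_ci(data, fit, 1, 0.90)
        assert ci.lower == pytest.approx(above.min(), abs=0.01)
        assert ci.upper == pytest.approx(above.max(), abs=0.01)

    def test_asymptotic_agreement_with_wald(self):
        """At n = 2000 the profile and Wald widths agree within 2%."""
        model = TrueModel(0.0, (np.log(2.0),), "normal")
        data = sample_quota(model, SamplingSpec(2000, 1000, 101))
        fit = fit_firth(data, STRICT)
        pci = profile_ci(data, fit, 1, 0.90)
        z = 1.6448536269514722
        wald_width = 2 * z * fit.standard_errors[1]
        assert pci.width == pytest.approx(wald_width, rel=0.02)

    def test_requires_firth_fit(self, toys):
        with pytest.raises(ValueError):
            profile_ci(toys["cells_6446"], fit_ml(toys["cells_6446"]), 1, 0.90)


def test_convergence_presets_match_documented_values():
    assert CONVERGENCE_PRESETS["default"] == ConvergenceSpec(1e-8, 25)
    assert CONVERGENCE_PRESETS["typeI"] == ConvergenceSpec(1e-6, 25)
    assert CONVERGENCE_PRESETS["typeII"] == ConvergenceSpec(1e-10, 25)
    assert CONVERGENCE_PRESETS["typeIII"] == ConvergenceSpec(1e-10, 50)
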
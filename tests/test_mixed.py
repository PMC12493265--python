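import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

import statsmodels.api as sm

import soilheat as sh
from soilheat.design import build_model_matrix
from soilheat.mixed import (
    GaussianMixedModel,
    MixedFitResults,
    NegativeBinomialMixedModel,
    PercentChange,
)


def _nb_loglik_direct(y, log_mu, log_k):
    k = np.exp(log_k)
    mu = np.exp(log_mu)
    return np.sum(
        special.gammaln(y + k) - special.gammaln(k) - special.gammaln(y + 1)
        + k * (np.log(k) - np.log(k + mu)) + y * (np.log(mu) - np.log(k + mu))
    )


class TestNegativeBinomialFit:
    def test_intercept_only_matches_direct_mle(self):
        rng = np.random.default_rng(7)
        mu, k = 12.0, 2.0
        y = rng.negative_binomial(k, k / (k + mu), size=300)
        fit = NegativeBinomialMixedModel(y, np.ones((len(y), 1))).fit()
        # independent two-parameter numeric MLE with a different optimiser
        res = optimize.minimize(
            lambda th: -_nb_loglik_direct(y, th[0], th[1]),
            x0=np.array([np.log(y.mean() + 1.0), 0.5]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        assert fit.params.iloc[0] == pytest.approx(res.x[0], abs=1e-4)
        assert np.log(fit.k) == pytest.approx(res.x[1], abs=1e-4)

    def test_loglik_dominates_poisson_submodel(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=150)
        mu = np.exp(1.0 + 0.5 * x)
        y = rng.negative_binomial(1.2, 1.2 / (1.2 + mu))
        X = np.column_stack([np.ones_like(x), x])
        nb = NegativeBinomialMixedModel(y, X).fit()
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert nb.llf >= pois.llf - 1e-6

    def test_offset_shifts_intercept(self):
        rng = np.random.default_rng(9)
        off = rng.normal(0, 0.5, size=400)
        y = rng.poisson(np.exp(1.0 + off))
        fit = NegativeBinomialMixedModel(y, np.ones((400, 1)), offset=off).fit()
        assert fit.params.iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            NegativeBinomialMixedModel(np.array([1.0, -2.0]), np.ones((2, 1)))
        with pytest.raises(ValueError):
            NegativeBinomialMixedModel(np.array([1.5, 2.0]), np.ones((2, 1)))

    def test_boundary_variance_reduces_to_fixed_model(self):
        rng = np.random.default_rng(10)
        y = rng.poisson(10.0, size=200)
        groups = np.repeat(np.arange(4), 50)
        fit = NegativeBinomialMixedModel(y, np.ones((200, 1)), groups=groups).fit()
        # no group structure in the data: variance collapses to ~0
        assert fit.sigma_u < 0.05
        if fit.boundary:
            assert fit.sigma_u == 0.0

    def test_random_intercept_variance_recovered(self):
        rng = np.random.default_rng(11)
        sigma_u, n_groups, per = 0.6, 40, 25
        u = rng.normal(0, sigma_u, n_groups)
        groups = np.repeat(np.arange(n_groups), per)
        y = rng.poisson(np.exp(2.0 + u[groups]))
        fit = NegativeBinomialMixedModel(y, np.ones((len(y), 1)), groups=groups).fit()
        assert fit.sigma_u == pytest.approx(sigma_u, rel=0.3)
        assert fit.params.iloc[0] == pytest.approx(2.0, abs=0.3)


class TestGaussianFit:
    def test_constant_response(self):
        y = np.full(30, 5.0)
        groups = np.repeat([0, 1, 2], 10)
        fit = GaussianMixedModel(y, np.ones((30, 1)), groups=groups).fit()
        assert fit.params.iloc[0] == pytest.approx(5.0)
        assert fit.scale == 0.0

    def test_balanced_oneway_reml_matches_anova_estimator(self):
        rng = np.random.default_rng(12)
        a, n = 8, 10
        sigma_u, sigma_e = 1.5, 1.0
        u = rng.normal(0, sigma_u, a)
        groups = np.repeat(np.arange(a), n)
        y = 3.0 + u[groups] + rng.normal(0, sigma_e, a * n)
        fit = GaussianMixedModel(y, np.ones((a * n, 1)), groups=groups).fit(reml=True)
        # method-of-moments (ANOVA) estimator for the balanced one-way layout
        ybar_g = np.array([y[groups == g].mean() for g in range(a)])
        msb = n * np.sum((ybar_g - y.mean()) ** 2) / (a - 1)
        msw = sum(np.sum((y[groups == g] - ybar_g[g]) ** 2) for g in range(a)) / (a * (n - 1))
        var_u_anova = (msb - msw) / n
        assert fit.scale == pytest.approx(msw, rel=1e-4)
        assert fit.sigma_u**2 == pytest.approx(var_u_anova, rel=1e-3)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(13)
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        groups = rng.integers(0, 4, n)
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 1, n)
        perm = rng.permutation(n)
        f1 = GaussianMixedModel(y, X, groups=groups).fit()
        f2 = GaussianMixedModel(y[perm], X[perm], groups=groups[perm]).fit()
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-6)


@pytest.fixture(scope="module")
def factorial_fit(h2_frame):
    rng = np.random.default_rng(14)
    mm = build_model_matrix(h2_frame, groups="site")
    beta = rng.normal(0, 0.5, mm.shape[1])
    beta[0] = 2.0
    y = rng.poisson(np.exp(mm.matrix @ beta))
    return NegativeBinomialMixedModel(y, mm).fit(), mm


class TestMarginalMeans:
    def test_reference_cell_equals_intercept(self, factorial_fit):
        fit, mm = factorial_fit
        grid = fit.marginal_means(["elevation", "season", "treatment"])
        ref = grid[(grid.elevation == "high") & (grid.season == "spring") & (grid.treatment == "control")]
        assert ref["estimate"].iloc[0] == pytest.approx(fit.params["Intercept"])

    def test_grid_size_is_product_of_levels(self, factorial_fit):
        fit, _ = factorial_fit
        assert len(fit.marginal_means(["elevation", "season", "treatment"])) == 12
        assert len(fit.marginal_means(["season"])) == 3

    def test_equivariance_under_reference_change(self, h2_frame):
        rng = np.random.default_rng(15)
        mm_a = build_model_matrix(h2_frame)
        beta = rng.normal(0, 0.4, mm_a.shape[1])
        beta[0] = 2.5
        y = rng.poisson(np.exp(mm_a.matrix @ beta))
        mm_b = build_model_matrix(
            h2_frame, reference={"elevation": "low", "season": "autumn", "treatment": "extreme_heat"}
        )
        fit_a = NegativeBinomialMixedModel(y, mm_a).fit()
        fit_b = NegativeBinomialMixedModel(y, mm_b).fit()
        ga = fit_a.marginal_means(["elevation", "treatment"]).set_index(["elevation", "treatment"])
        gb = fit_b.marginal_means(["elevation", "treatment"]).set_index(["elevation", "treatment"])
        np.testing.assert_allclose(
            ga["estimate"], gb.loc[ga.index, "estimate"], atol=5e-3
        )

    def test_intercept_only_single_cell(self):
        rng = np.random.default_rng(16)
        y = rng.poisson(5.0, 60)
        fit = NegativeBinomialMixedModel(y, np.ones((60, 1))).fit()
        with pytest.raises(ValueError):
            fit.marginal_means(["treatment"])  # no design attached


def _manual_results(delta, se_delta, link="log"):
    """Two-cell (treatment-only) results object with known contrast."""
    units = pd.DataFrame(
        {
            "treatment": ["control", "extreme_heat"] * 2,
            "unit_id": [f"u{i}" for i in range(4)],
        }
    ).set_index("unit_id")
    mm = build_model_matrix(units, factors=("treatment",), groups=None)
    params = pd.Series([1.0, delta], index=mm.columns)
    cov = pd.DataFrame(
        [[0.0, 0.0], [0.0, se_delta**2]], index=mm.columns, columns=mm.columns
    )
    return MixedFitResults(
        params, cov, link=link, k=1.0 if link == "log" else None,
        scale=None if link == "log" else 1.0, sigma_u=0.0, llf=0.0,
        converged=True, grad_norm=0.0, boundary=False, design=mm, n_obs=4,
    )


class TestPercentChange:
    def test_zero_difference_is_zero_percent(self):
        pc = _manual_results(0.0, 0.1).percent_change({})
        assert pc.percent == pytest.approx(0.0)

    def test_delta_method_worked_example(self):
        # delta = -1.17118, SE = 0.10 -> -69.0% +/- 3.10%
        pc = _manual_results(-1.17118, 0.10).percent_change({})
        assert pc.percent == pytest.approx(100 * (np.exp(-1.17118) - 1), abs=1e-9)
        assert pc.percent == pytest.approx(-69.0, abs=0.01)
        assert pc.se_percent == pytest.approx(100 * np.exp(-1.17118) * 0.10, abs=1e-9)
        assert pc.se_percent == pytest.approx(3.10, abs=0.005)

    def test_doubling_with_zero_se(self):
        pc = _manual_results(np.log(2.0), 0.0).percent_change({})
        assert pc.percent == pytest.approx(100.0)
        assert pc.se_percent == pytest.approx(0.0)

    def test_identity_link_refuses_percent(self):
        pc = _manual_results(1.3, 0.2, link="identity").percent_change({})
        assert pc.percent is None
        assert pc.delta == pytest.approx(1.3)
        assert pc.se_delta == pytest.approx(0.2)

    @pytest.mark.parametrize("delta, se", [(-1.0, 0.1), (0.5, 0.2), (-2.0, 0.2)])
    def test_delta_method_matches_parametric_bootstrap(self, delta, se):
        rng = np.random.default_rng(17)
        draws = rng.normal(delta, se, 10_000)
        boot_sd = np.std(100 * np.expm1(draws), ddof=1)
        pc = _manual_results(delta, se).percent_change({})
        assert pc.se_percent == pytest.approx(boot_sd, rel=0.05)
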
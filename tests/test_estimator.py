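"""Estimator behaviour: the ML discrepancy, gradients, self-consistency,
standard errors, derived means, and nested tests."""

import numpy as np
import pytest
from scipy import stats

import arcfa
from arcfa.covariance import ParameterIndex
from arcfa.estimate import _objective, NotNestedError, start_vector
from tests.conftest import random_pd


class TestMlDiscrepancy:
    def test_zero_at_equality(self, rng):
        S = random_pd(rng, 6)
        assert arcfa.ml_discrepancy(S, S.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_univariate_closed_form(self):
        assert arcfa.ml_discrepancy(np.array([[2.0]]), np.array([[1.0]])) == pytest.approx(
            1.0 - np.log(2.0)
        )

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(25):
            p = rng.integers(2, 8)
            F = arcfa.ml_discrepancy(random_pd(rng, p), random_pd(rng, p))
            assert F >= 0.0

    def test_matches_loglikelihood_ratio_oracle(self, rng):
        """F equals -2/(N-1) times the log-likelihood ratio to the
        saturated model under the multivariate-normal density."""
        p, n = 4, 200
        sigma_true = random_pd(rng, p)
        y = rng.multivariate_normal(np.zeros(p), sigma_true, size=n)
        S = y.T @ y / n  # ML covariance of known-mean data: the saturated MLE
        sigma_model = random_pd(rng, p)
        ll_model = stats.multivariate_normal(np.zeros(p), sigma_model).logpdf(y).sum()
        ll_sat = stats.multivariate_normal(np.zeros(p), S).logpdf(y).sum()
        expected = -2.0 * (ll_model - ll_sat) / n
        got = arcfa.ml_discrepancy(S, sigma_model)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_singular_sigma_is_inadmissible_not_fatal(self, rng):
        S = random_pd(rng, 3)
        assert np.isinf(arcfa.ml_discrepancy(S, np.zeros((3, 3))))


class TestGradient:
    def test_analytic_matches_finite_differences(self, layout, moments):
        spec = arcfa.build_ar_cfa(layout, "adjacent_plus_construct")
        index = ParameterIndex.for_spec(spec)
        m = moments.reorder(layout.names)
        sign, logdet_s = np.linalg.slogdet(m.S)
        var_slots = np.array([k for k, kd in enumerate(index.kinds) if kd == "residual_var"])
        theta0 = start_vector(index, m)
        phi = theta0.copy()
        phi[var_slots] = np.log(theta0[var_slots])
        rng = np.random.default_rng(3)
        phi = phi + rng.normal(scale=0.05, size=phi.shape)
        f0, grad = _objective(phi, index, m.S, logdet_s, var_slots)
        h = 1e-6
        for k in rng.choice(phi.size, size=12, replace=False):
            up, dn = phi.copy(), phi.copy()
            up[k] += h
            dn[k] -= h
            fd = (_objective(up, index, m.S, logdet_s, var_slots)[0]
                  - _objective(dn, index, m.S, logdet_s, var_slots)[0]) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=2e-4, abs=1e-8)


class TestFit:
    def test_converged_with_small_gradient(self, ar_fit):
        assert ar_fit.converged
        assert ar_fit.grad_norm < 1e-6
        assert ar_fit.hessian_pd

    def test_self_consistency_refit(self, layout):
        """Refitting a model to its own implied covariance recovers the
        parameters (F_min ~ 0)."""
        pop = arcfa.make_population(ar=0.2, loading=0.7, factor_corr=0.25, layout=layout)
        moments = arcfa.SampleMoments(S=pop.sigma, names=layout.names, n=5000)
        refit = arcfa.fit(pop.spec, moments)
        assert refit.converged
        assert refit.f_min < 1e-8
        assert np.allclose(refit.theta, pop.theta, atol=1e-4)

    def test_chi2_scaling(self, ic_fit):
        assert ic_fit.chi2 == pytest.approx((ic_fit.n - 1) * ic_fit.f_min)

    def test_se_scales_inverse_sqrt_n(self, layout, moments):
        """Doubling the effective N shrinks every SE by exactly sqrt(2)
        when the same S is refit (information is linear in N-1)."""
        spec = arcfa.build_ic_cfa(layout)
        f1 = arcfa.fit(spec, moments)
        m2 = arcfa.SampleMoments(S=moments.S, names=moments.names, n=2 * moments.n - 1)
        f2 = arcfa.fit(spec, m2)
        ratio = f1.se / f2.se
        assert np.allclose(ratio, np.sqrt(2.0), rtol=1e-3)


class TestStandardize:
    def test_factor_correlations_equal_raw_psi(self, ar_fit):
        """Under unit-variance identification the standardized factor
        correlation is the raw psi entry."""
        table = arcfa.standardize(ar_fit)
        fc = table[(table.matrix == "factor_cov") & table.free]
        assert np.allclose(fc["estimate"], fc["std"])

    def test_ic_loading_e1(self, ic_fit):
        table = arcfa.standardize(ic_fit)
        row = table[table.label == "lambda[e1~E]"].iloc[0]
        assert row["std"] == pytest.approx(0.68, abs=0.01)

    def test_loading_and_residual_partition_variance(self, ic_fit):
        """For the IC-CFA, std loading^2 + std residual variance = 1."""
        table = arcfa.standardize(ic_fit)
        loads = table[table.matrix == "loading"].sort_values("row")["std"].to_numpy()
        rvars = table[table.matrix == "residual_var"].sort_values("row")["std"].to_numpy()
        assert np.allclose(loads**2 + rvars, 1.0, atol=1e-8)


class TestDerivedMean:
    def test_singleton_group_is_the_coefficient(self, ar_fit):
        d = arcfa.derived_group_mean(ar_fit, [("e2", "a2")])
        assert d.estimate == pytest.approx(ar_fit.ar_estimate("e2", "a2"))
        assert d.se == pytest.approx(ar_fit.param_se("kappa[e2->a2]"), rel=1e-9)
        assert d.t == pytest.approx(d.estimate / d.se)

    def test_empty_group_rejected(self, ar_fit):
        with pytest.raises(ValueError):
            arcfa.derived_group_mean(ar_fit, [])

    def test_c_to_n_average_matches_members(self, ar_fit):
        group = [("c2", "n2"), ("c3", "n3"), ("c4", "n4")]
        d = arcfa.derived_group_mean(ar_fit, group)
        members = [ar_fit.ar_estimate(s, t) for s, t in group]
        assert d.estimate == pytest.approx(np.mean(members))


class TestModelComparison:
    def test_identical_specs_zero_difference(self, ic_fit):
        out = arcfa.likelihood_ratio_test(ic_fit, ic_fit)
        assert out["delta_chi2"] == 0.0
        assert out["delta_df"] == 0

    def test_ic_vs_ar_delta_df(self, ic_fit, ar_fit):
        out = arcfa.likelihood_ratio_test(ic_fit, ar_fit)
        assert out["delta_df"] == 34
        assert out["delta_chi2"] > 0
        assert out["p_value"] < 0.001

    def test_nested_test_refused_for_rc_vs_ar(self, layout, moments, ar_fit):
        rc = arcfa.build_rc_cfa(ar_fit.spec)
        rc_fit = arcfa.fit(rc, moments)
        with pytest.raises(NotNestedError):
            arcfa.likelihood_ratio_test(rc_fit, ar_fit)
        out = arcfa.compare_fits(rc_fit, ar_fit)
        assert out["nested"] is False
        assert out["p_value"] is None
        # same df, but the AR structure fits these moments better
        assert out["delta_df"] == 0
        assert out["delta_aic"] > 0 and out["delta_bic"] > 0

    def test_constraint_scheme_delta_dfs(self, layout, moments, ar_fit):
        for scheme, ddf in [("by_type", 20), ("by_type_and_scoring", 17)]:
            constrained = arcfa.apply_equality_constraints(ar_fit.spec, scheme)
            cfit = arcfa.fit(constrained, moments)
            out = arcfa.likelihood_ratio_test(cfit, ar_fit)
            assert out["delta_df"] == ddf
            assert out["delta_chi2"] > 0
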
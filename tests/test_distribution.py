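"""Distribution core: closed forms against independent oracles and the law's
structural identities (scale mixture, alpha-monotonicity, hazard
characterization, IW limit)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import invweibull, kstest

from alphaiw import (
    AIWParams, IWParams, aiw_cdf, aiw_hazard, aiw_logpdf, aiw_mean,
    aiw_moment, aiw_pdf, aiw_quantile, aiw_rvs, aiw_sf, aiw_variance,
    alpha_monotone_check, characterization_residual, iw_cdf, iw_logpdf,
    iw_pdf, iw_quantile, iw_rvs, iw_sup_distance, mixture_pdf_oracle,
    reciprocal_transform_pdf,
)
from alphaiw.distribution import _aiw_pdf_gamma_cdf_form

UNIT = AIWParams(1.0, 1.0, 1.0)

positive_param = st.floats(0.3, 5.0)
param_triples = st.tuples(positive_param, positive_param, positive_param)


class TestPdf:
    def test_reference_value_at_unit_params(self):
        # gamma(2, 1) = 1 - 2/e
        assert aiw_pdf(1.0, UNIT) == pytest.approx(1.0 - 2.0 / np.e, abs=1e-12)

    def test_normalizes_to_one(self, study_params):
        total, err = integrate.quad(lambda t: aiw_pdf(t, study_params),
                                    0, np.inf, limit=300)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_two_codings_agree(self, study_params, log_grid):
        a = aiw_pdf(log_grid, study_params)
        b = _aiw_pdf_gamma_cdf_form(log_grid, study_params)
        np.testing.assert_allclose(a, b, rtol=0, atol=1e-12)

    def test_matches_mixture_quadrature_oracle(self, study_params):
        grid = np.logspace(-1.5, 1.5, 9)
        oracle = np.array([mixture_pdf_oracle(t, study_params) for t in grid])
        np.testing.assert_allclose(aiw_pdf(grid, study_params), oracle,
                                   atol=1e-8, rtol=1e-8)

    def test_rejects_out_of_support(self):
        with pytest.raises(ValueError):
            aiw_pdf(0.0, UNIT)
        with pytest.raises(ValueError):
            aiw_pdf(np.inf, UNIT)

    def test_masked_logpdf_outside_support(self):
        lp = aiw_logpdf(np.array([-1.0, 0.0, 1.0]), UNIT, strict=False)
        assert lp[0] == -np.inf and lp[1] == -np.inf and np.isfinite(lp[2])


class TestCdf:
    def test_reference_value_and_limits(self):
        assert aiw_cdf(1.0, UNIT) == pytest.approx(1.0 - np.exp(-1.0), abs=1e-12)
        assert aiw_cdf(-3.0, UNIT) == 0.0
        assert aiw_cdf(1e-12, AIWParams(2, 2, 1)) == pytest.approx(0.0, abs=1e-12)
        assert aiw_cdf(1e9, AIWParams(2, 2, 1)) == pytest.approx(1.0, abs=1e-8)

    def test_cdf_equals_numeric_integral_of_pdf(self):
        params = AIWParams(2.0, 1.0, 1.0)
        val, _ = integrate.quad(lambda t: aiw_pdf(t, params), 0, 1.0, limit=200)
        assert aiw_cdf(1.0, params) == pytest.approx(val, abs=1e-10)

    def test_iw_plus_scaled_density_identity(self, study_params, log_grid):
        # F(t) = F_IW(t) + (t/alpha) f(t)
        lhs = aiw_cdf(log_grid, study_params)
        rhs = (iw_cdf(log_grid, study_params.iw_limit())
               + log_grid / study_params.alpha * aiw_pdf(log_grid, study_params))
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(triple=param_triples, t=st.floats(1e-2, 1e2))
    def test_cdf_bounds_and_identity_property(self, triple, t):
        params = AIWParams(*triple)
        F = aiw_cdf(t, params)
        assert 0.0 <= F <= 1.0
        rhs = iw_cdf(t, params.iw_limit()) + t / params.alpha * aiw_pdf(t, params)
        assert F == pytest.approx(rhs, abs=1e-10)


class TestHazard:
    def test_definition_holds(self, study_params, log_grid):
        h = aiw_hazard(log_grid, study_params)
        resid = h * aiw_sf(log_grid, study_params) - aiw_pdf(log_grid, study_params)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_reference_value(self):
        assert aiw_hazard(1.0, UNIT) == pytest.approx((1 - 2 / np.e) / np.exp(-1),
                                                      abs=1e-10)

    def test_non_monotone_shape_exists(self):
        # this setting produces a change of direction in the hazard profile
        params = AIWParams(0.9, 1.7, 1.0)
        t = np.logspace(-1, 1, 400)
        dh = np.diff(aiw_hazard(t, params))
        assert np.any(dh > 0) and np.any(dh < 0)

    def test_deep_tail_raises(self):
        with pytest.raises(OverflowError):
            aiw_hazard(1e12, AIWParams(1.0, 3.0, 1.0))


class TestQuantile:
    def test_round_trip_through_cdf(self):
        p = aiw_cdf(1.0, UNIT)
        assert aiw_quantile(p, UNIT) == pytest.approx(1.0, abs=1e-9)

    def test_median_defining_property(self):
        params = AIWParams(2.0, 2.0, 1.0)
        med = aiw_quantile(0.5, params)
        assert abs(aiw_cdf(med, params) - 0.5) <= 1e-10

    def test_small_p_bracket(self):
        params = AIWParams(1.5, 0.8, 1.0)
        q = aiw_quantile(1e-6, params)
        assert q > 0 and abs(aiw_cdf(q, params) - 1e-6) <= 1e-10

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                aiw_quantile(bad, UNIT)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(triple=param_triples, p=st.floats(1e-4, 1 - 1e-4))
    def test_round_trip_property(self, triple, p):
        params = AIWParams(*triple)
        assert aiw_cdf(aiw_quantile(p, params), params) == pytest.approx(p, abs=1e-9)


class TestMoments:
    def test_closed_form_value(self):
        # sigma^{1/2} * (1/2) * Gamma(1/2) = sqrt(pi)/2
        assert aiw_moment(1, AIWParams(1, 2, 1)) == pytest.approx(
            np.sqrt(np.pi) / 2, abs=1e-12)

    def test_approaches_iw_mean_from_below(self):
        iw_mean_ref = invweibull(c=2.0, scale=1.0).mean()
        vals = [aiw_moment(1, AIWParams(a, 2.0, 1.0)) for a in (5, 50, 500)]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] < iw_mean_ref
        assert vals[-1] == pytest.approx(iw_mean_ref, rel=3e-3)

    def test_nonexistent_moment_raises(self):
        with pytest.raises(ValueError):
            aiw_moment(2.0, AIWParams(1.0, 2.0, 1.0))
        with pytest.raises(ValueError):
            aiw_moment(3.0, AIWParams(1.0, 2.0, 1.0))

    def test_monte_carlo_agreement(self):
        params = AIWParams(1.0, 2.0, 1.0)
        sample = aiw_rvs(10**6, params, seed=20240917).values
        se = sample.std(ddof=1) / np.sqrt(sample.size)
        assert abs(sample.mean() - aiw_mean(params)) < 3 * se

    def test_variance_positive(self):
        assert aiw_variance(AIWParams(1.5, 3.0, 2.0)) > 0


class TestSampling:
    def test_seeded_reproducibility(self):
        params = AIWParams(1.7, 2.5, 1.0)
        s1 = aiw_rvs(200, params, seed=42).values
        s2 = aiw_rvs(200, params, seed=42).values
        np.testing.assert_array_equal(s1, s2)

    def test_all_positive_and_n_validated(self):
        assert np.all(aiw_rvs(50, UNIT, seed=1).values > 0)
        with pytest.raises(ValueError):
            aiw_rvs(0, UNIT, seed=1)

    def test_empirical_cdf_matches_analytic(self, study_params):
        sample = aiw_rvs(20000, study_params, seed=7).values
        res = kstest(sample, lambda t: aiw_cdf(t, study_params))
        # 1% critical value of the KS statistic ~ 1.63 / sqrt(n)
        assert res.statistic < 1.63 / np.sqrt(sample.size)


class TestBaselineIW:
    def test_matches_scipy_invweibull(self):
        params = IWParams(beta=2.5, sigma=3.0)
        ref = invweibull(c=2.5, scale=3.0 ** (1 / 2.5))
        t = np.logspace(-0.5, 1, 20)
        np.testing.assert_allclose(iw_pdf(t, params), ref.pdf(t), rtol=1e-12)
        np.testing.assert_allclose(iw_cdf(t, params), ref.cdf(t), rtol=1e-12)
        p = np.linspace(0.05, 0.95, 10)
        np.testing.assert_allclose(iw_quantile(p, params), ref.ppf(p), rtol=1e-12)

    def test_cdf_at_scale_point(self):
        for b in (0.5, 1.0, 3.7):
            params = IWParams(beta=b, sigma=2.0)
            assert iw_cdf(2.0 ** (1 / b), params) == pytest.approx(np.exp(-1),
                                                                   abs=1e-14)

    def test_quantile_round_trip(self):
        params = IWParams(beta=1.3, sigma=0.7)
        t = np.array([0.2, 1.0, 4.0])
        np.testing.assert_allclose(iw_quantile(iw_cdf(t, params), params), t,
                                   rtol=1e-12)

    def test_seeded_sampling(self):
        params = IWParams(beta=2.0, sigma=1.0)
        np.testing.assert_array_equal(iw_rvs(20, params, seed=3).values,
                                      iw_rvs(20, params, seed=3).values)


class TestStructuralIdentities:
    def test_alpha_monotone_inequality(self, study_params):
        grid = np.logspace(-2, 2, 200)
        assert alpha_monotone_check(study_params, grid) <= 1e-6

    def test_alpha_monotone_single_point(self):
        assert np.isfinite(alpha_monotone_check(UNIT, [1.0]))

    def test_hazard_characterization_residual(self):
        params = AIWParams(1.5, 0.8, 1.0)
        grid = np.logspace(-0.5, 0.7, 50)
        assert characterization_residual(params, grid) <= 1e-4

    def test_characterization_at_single_point(self):
        assert characterization_residual(UNIT, [1.0]) <= 1e-6

    def test_reciprocal_transform_density(self):
        params = AIWParams(1.5, 0.8, 1.0)
        total, _ = integrate.quad(lambda z: reciprocal_transform_pdf(z, params),
                                  0, np.inf, limit=300)
        assert total == pytest.approx(1.0, abs=1e-7)
        assert reciprocal_transform_pdf(1.0, params) == pytest.approx(
            aiw_pdf(1.0, params), abs=1e-14)

    def test_reciprocal_draws_match_transform(self):
        params = AIWParams(2.0, 1.5, 1.0)
        z = 1.0 / aiw_rvs(20000, params, seed=11).values
        cdf_z = lambda zz: aiw_sf(1.0 / np.asarray(zz), params)
        res = kstest(z, cdf_z)
        assert res.statistic < 1.63 / np.sqrt(z.size)


class TestIWLimit:
    def test_sup_distance_decreasing_in_alpha(self):
        gaps = [iw_sup_distance(AIWParams(a, 2.0, 1.0))
                for a in (10, 100, 1000, 10000)]
        assert all(g1 > g2 for g1, g2 in zip(gaps, gaps[1:]))
        assert gaps[-1] <= 0.01

    def test_large_alpha_cdf_close_to_iw(self):
        params = AIWParams(1e4, 2.0, 1.0)
        t = np.logspace(-1, 1, 100)
        gap = np.max(np.abs(aiw_cdf(t, params) - iw_cdf(t, params.iw_limit())))
        assert gap <= 0.01


class TestParams:
    def test_positivity_enforced(self):
        for bad in [(-1, 1, 1), (1, 0, 1), (1, 1, -2), (np.nan, 1, 1)]:
            with pytest.raises(ValueError):
                AIWParams(*bad)

    def test_submodel_constructors(self):
        assert AIWParams.inverse_exponential(2.0, 3.0).beta == 1.0
        assert AIWParams.inverse_rayleigh(2.0, 3.0).beta == 2.0
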
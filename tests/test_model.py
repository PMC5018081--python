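import numpy as np
import pytest
from scipy import integrate, stats

import capmotion as cm
from capmotion.datasets import PUBLISHED_SIMPLIFIED_PROFILE
from capmotion.model import TipDistanceResults

RNG = np.random.default_rng(2024)


def _random_profile(rng):
    d1 = rng.uniform(0, 10)
    d2 = d1 + rng.uniform(0, 15)
    return cm.KProfile(d1, d2, rng.uniform(-0.3, 0.4), rng.uniform(-0.3, 0.1))


class TestKProfile:
    def test_reference_profile_evaluations(self):
        prof = PUBLISHED_SIMPLIFIED_PROFILE
        assert prof.k(0) == pytest.approx(0.293)
        assert prof.k(20) == pytest.approx(-0.098)
        assert prof.k(5) == pytest.approx(0.293 - (0.391 / 14.95) * 5, abs=1e-12)
        assert prof.k(5) == pytest.approx(0.163, abs=1e-3)  # matches the 0.026-rounded slope

    def test_profile_is_continuous_at_breakpoints(self):
        prof = cm.KProfile(3.0, 12.0, 0.25, -0.1)
        for d in (3.0, 12.0):
            eps = 1e-9
            assert prof.k(d - eps) == pytest.approx(prof.k(d + eps), abs=1e-6)

    def test_invalid_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            cm.KProfile(5.0, 2.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            cm.KProfile(-1.0, 2.0, 0.1, 0.1)


class TestCumulativeK:
    def test_constant_profile_integral(self):
        prof = cm.KProfile(0.0, 0.0, 0.2, 0.2)
        for d in (0.0, 1.0, 7.5):
            assert cm.cumulative_k(prof, d) == pytest.approx(0.2 * d)

    def test_step_profile_closed_form(self):
        prof = cm.KProfile(5.0, 5.0, 0.3, -0.1)
        for d in (2.0, 5.0, 9.0):
            expected = 0.3 * min(d, 5.0) + (-0.1) * max(0.0, d - 5.0)
            assert cm.cumulative_k(prof, d) == pytest.approx(expected)

    def test_zero_at_origin_and_quadrature_agreement(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            prof = _random_profile(rng)
            assert cm.cumulative_k(prof, 0.0) == 0.0
            for d in rng.uniform(0, 40, 3):
                ref, _ = integrate.quad(prof.k, 0, d, points=[prof.d1, prof.d2], limit=200)
                assert cm.cumulative_k(prof, d) == pytest.approx(ref, abs=1e-8)


class TestLogLikelihood:
    def test_flat_profile_is_uniform(self):
        prof = cm.KProfile(0.0, 1.0, 0.0, 0.0)
        d = np.array([1.0, 5.0, 17.3])
        assert cm.log_likelihood(prof, d, d_max=20.0) == pytest.approx(-3 * np.log(20.0))

    def test_constant_negative_k_is_truncated_exponential(self):
        c, d_max = -0.15, 50.0
        prof = cm.KProfile(0.0, 0.0, c, c)
        d = np.array([0.5, 3.0, 10.0, 30.0])
        z = (np.exp(c * d_max) - 1) / c
        expected = float(np.sum(c * d) - len(d) * np.log(z))
        assert cm.log_likelihood(prof, d, d_max=d_max) == pytest.approx(expected, abs=1e-9)

    def test_matches_adaptive_quadrature_normalisation(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            prof = _random_profile(rng)
            d_max = 50.0
            d = rng.uniform(0, d_max, 40)
            z, _ = integrate.quad(
                lambda u: np.exp(cm.cumulative_k(prof, u)), 0, d_max,
                points=[prof.d1, prof.d2], limit=400,
            )
            expected = float(np.sum(cm.cumulative_k(prof, d)) - len(d) * np.log(z))
            assert cm.log_likelihood(prof, d, d_max=d_max) == pytest.approx(expected, abs=1e-6)

    def test_distance_outside_domain_rejected(self):
        prof = cm.KProfile(0.0, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            cm.log_likelihood(prof, [25.0], d_max=20.0)


class TestDensity:
    def test_density_normalises_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            prof = _random_profile(rng)
            total, _ = integrate.quad(
                lambda u: cm.steady_state_density(prof, u, 60.0), 0, 60.0,
                points=[prof.d1, prof.d2], limit=400,
            )
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_constant_shift_in_k_tilts_density_by_exponential(self):
        prof = cm.KProfile(2.0, 10.0, 0.2, -0.1)
        shift = 0.05
        shifted = cm.KProfile(2.0, 10.0, 0.25, -0.05)
        d = np.linspace(0.1, 40, 7)
        ratio = cm.steady_state_density(shifted, d, 40.0) / cm.steady_state_density(prof, d, 40.0)
        # ratio proportional to exp(shift * d); normalisation cancels in ratios of ratios
        np.testing.assert_allclose(np.diff(np.log(ratio)) / np.diff(d), shift, atol=1e-8)


class TestSampling:
    def test_uniform_case_passes_ks(self):
        prof = cm.KProfile(0.0, 1.0, 0.0, 0.0)
        x = cm.sample_steady_state(prof, 10_000, 30.0, seed=42)
        p = stats.kstest(x, "uniform", args=(0, 30.0)).pvalue
        assert p > 0.01

    def test_truncated_exponential_case_passes_ks(self):
        c, d_max = -0.2, 40.0
        prof = cm.KProfile(0.0, 0.0, c, c)
        x = cm.sample_steady_state(prof, 10_000, d_max, seed=43)
        cdf = lambda v: (1 - np.exp(c * v)) / (1 - np.exp(c * d_max))
        assert stats.kstest(x, cdf).pvalue > 0.01

    def test_far_field_log_density_slope(self):
        prof = PUBLISHED_SIMPLIFIED_PROFILE
        x = cm.sample_steady_state(prof, 200_000, 80.0, seed=44)
        edges = np.arange(20.0, 60.0, 2.0)
        hist, _ = np.histogram(x, bins=edges)
        mid = (edges[:-1] + edges[1:]) / 2
        slope = stats.linregress(mid, np.log(hist)).slope
        assert slope == pytest.approx(-0.098, abs=0.01)

    def test_reproducible_under_fixed_seed(self):
        prof = PUBLISHED_SIMPLIFIED_PROFILE
        a = cm.sample_steady_state(prof, 100, 60.0, seed=7)
        b = cm.sample_steady_state(prof, 100, 60.0, seed=7)
        np.testing.assert_array_equal(a, b)


class TestFit:
    def test_likelihood_peaks_at_truth_versus_perturbations(self):
        prof = PUBLISHED_SIMPLIFIED_PROFILE
        x = cm.sample_steady_state(prof, 30_000, 60.0, seed=3)
        model = cm.TipDistanceModel(x, d_max=60.0)
        at_truth = model.loglike(prof.params)
        for delta in ([0, 2, 0, 0], [0, 0, 0.05, 0], [0, 0, 0, 0.03], [3, 3, 0, 0]):
            assert at_truth > model.loglike(prof.params + np.array(delta, float))

    def test_degenerate_exponential_fits_flat_profile(self):
        """Data from a constant-k density must yield an effectively flat k(d)
        over the range the data occupy (the breakpoints are unidentified)."""
        c = -0.1
        prof = cm.KProfile(0.0, 0.0, c, c)
        x = cm.sample_steady_state(prof, 15_000, 60.0, seed=9)
        res = cm.TipDistanceModel(x, d_max=60.0).fit()
        quantiles = np.quantile(x, [0.05, 0.25, 0.5, 0.75, 0.95])
        fitted_k = res.profile.k(quantiles)
        np.testing.assert_allclose(fitted_k, c, atol=0.02)
        assert res.params[3] == pytest.approx(c, abs=0.01)

    def test_standard_errors_close_to_bootstrap_spread(self):
        prof = PUBLISHED_SIMPLIFIED_PROFILE
        rng = np.random.default_rng(17)
        x = cm.sample_steady_state(prof, 4000, 60.0, seed=18)
        res = cm.TipDistanceModel(x, d_max=60.0).fit(start_params=prof.params, multi_start=False)
        boot = []
        for _ in range(10):
            xb = rng.choice(x, size=len(x), replace=True)
            rb = cm.TipDistanceModel(xb, d_max=60.0).fit(
                start_params=res.params, multi_start=False
            )
            boot.append(rb.params)
        boot_sd = np.std(np.asarray(boot), axis=0, ddof=1)
        # compare the well-identified parameters (d2, k2)
        for i in (1, 3):
            assert res.bse[i] == pytest.approx(boot_sd[i], rel=0.5)

    def test_fit_mle_wrapper_and_summary(self):
        x = cm.sample_steady_state(PUBLISHED_SIMPLIFIED_PROFILE, 5000, 60.0, seed=21)
        res = cm.fit_mle(x, d_max=60.0)
        text = res.summary()
        assert "k1" in text and "log-likelihood" in text
        assert res.converged


class TestSimplify:
    @staticmethod
    def _results(params, ses):
        model = cm.TipDistanceModel(np.linspace(0.1, 50, 200), d_max=60.0)
        return TipDistanceResults(model, params, np.diag(np.square(ses)), -1.0, True)

    def test_insignificant_d1_pinned_to_zero(self):
        res = self._results([0.005, 14.95, 0.293, -0.098], [0.381, 0.18, 0.010, 0.001])
        simp = res.simplified()
        assert simp.d1 == 0.0
        assert simp.d2 == 14.95 and simp.k1 == 0.293 and simp.k2 == -0.098
        assert round((simp.k1 - simp.k2) / simp.d2, 3) == 0.026

    def test_significant_d1_left_unchanged(self):
        res = self._results([5.0, 14.95, 0.293, -0.098], [0.1, 0.18, 0.010, 0.001])
        assert res.simplified().d1 == 5.0

    def test_exactly_zero_d1_is_idempotent(self):
        res = self._results([0.0, 14.95, 0.293, -0.098], [0.3, 0.18, 0.010, 0.001])
        assert res.simplified().d1 == 0.0

    def test_zero_se_keeps_fitted_value_with_warning(self, caplog):
        import logging

        res = self._results([0.4, 14.95, 0.293, -0.098], [0.0, 0.18, 0.010, 0.001])
        with caplog.at_level(logging.WARNING, logger="capmotion.model"):
            assert res.simplified().d1 == pytest.approx(0.4)

    def test_simplify_refuses_unconverged_fit(self):
        model = cm.TipDistanceModel(np.linspace(0.1, 50, 200), d_max=60.0)
        res = TipDistanceResults(model, [1, 10, 0.1, -0.1], np.eye(4), -1.0, False)
        with pytest.raises(cm.errors.FitError):
            cm.simplify(res)
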
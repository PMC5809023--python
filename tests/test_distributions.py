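"""Closed-form density layer: values, moments, samplers, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from ddtcycle import (
    CheckpointParams,
    DDTModel,
    EMGModel,
    emg_pdf,
    shifted_wald_pdf,
    wald_moments,
    wald_pdf,
    wald_sample,
)
from ddtcycle.distributions import wald_cdf, wald_logpdf

positive = st.floats(min_value=0.02, max_value=5.0, allow_nan=False)


class TestWaldPdf:
    def test_value_where_exponent_vanishes(self, cp_slow):
        # at t = 1/mu the exponent is zero, so f = 1/(sigma*sqrt(2 pi t^3))
        expected = 1.0 / (0.1 * np.sqrt(2 * np.pi * 125.0))
        assert wald_pdf(5.0, cp_slow) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.3568, abs=5e-5)

    @pytest.mark.parametrize("t", [0.0, -1.0, -100.0])
    def test_zero_outside_support(self, t, cp_slow):
        assert wald_pdf(t, cp_slow) == 0.0

    def test_normalizes(self, cp_slow):
        total, _ = integrate.quad(lambda t: wald_pdf(t, cp_slow), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_matches_scipy_invgauss(self, cp_slow):
        """Independent route: scipy's inverse Gaussian with the mapped params."""
        t = np.linspace(0.5, 20, 200)
        lam = 1.0 / cp_slow.sigma**2
        ref = stats.invgauss.pdf(t, cp_slow.sigma**2 / cp_slow.mu, scale=lam)
        np.testing.assert_allclose(wald_pdf(t, cp_slow), ref, rtol=1e-10)

    def test_nonfinite_time_rejected(self, cp_slow):
        with pytest.raises(ValueError):
            wald_pdf(np.nan, cp_slow)

    @pytest.mark.parametrize("mu,sigma", [(0, 1), (-1, 1), (1, 0), (1, -2), (np.inf, 1)])
    def test_invalid_params_rejected(self, mu, sigma):
        with pytest.raises(ValueError):
            CheckpointParams(mu, sigma)


class TestWaldMoments:
    @pytest.mark.parametrize(
        "mu,sigma,mean,var,cv",
        [
            (0.2, 0.1, 5.0, 1.25, 0.2236067977),
            (0.25, 1.0, 4.0, 64.0, 2.0),
        ],
    )
    def test_known_values(self, mu, sigma, mean, var, cv):
        m, v, c = wald_moments(CheckpointParams(mu, sigma))
        assert m == pytest.approx(mean)
        assert v == pytest.approx(var)
        assert c == pytest.approx(cv)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(mu=positive, sigma=positive, c=st.floats(min_value=0.1, max_value=10))
    def test_cv_scale_invariance(self, mu, sigma, c):
        """CV = sigma/sqrt(mu) is invariant under (mu, sigma) -> (c mu, sqrt(c) sigma)."""
        cv1 = wald_moments(CheckpointParams(mu, sigma))[2]
        cv2 = wald_moments(CheckpointParams(c * mu, np.sqrt(c) * sigma))[2]
        assert cv1 == pytest.approx(cv2, rel=1e-9)


class TestShiftedWald:
    def test_zero_shift_is_identity(self, cp_slow):
        t = np.linspace(-1, 20, 100)
        np.testing.assert_array_equal(
            shifted_wald_pdf(t, cp_slow, 0.0), wald_pdf(t, cp_slow)
        )

    def test_translation_identity(self, cp_slow):
        assert shifted_wald_pdf(8.5, cp_slow, 3.5) == pytest.approx(
            wald_pdf(5.0, cp_slow), rel=1e-12
        )

    def test_zero_at_and_below_shift(self, cp_slow):
        assert shifted_wald_pdf(3.5, cp_slow, 3.5) == 0.0
        assert shifted_wald_pdf(1.0, cp_slow, 3.5) == 0.0

    def test_negative_shift_rejected(self, cp_slow):
        with pytest.raises(ValueError):
            shifted_wald_pdf(5.0, cp_slow, -0.1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        tau1=st.floats(min_value=0, max_value=3),
        tau2=st.floats(min_value=0, max_value=3),
        t=st.floats(min_value=0.1, max_value=30),
    )
    def test_shift_composition(self, tau1, tau2, t):
        p = CheckpointParams(0.2, 0.1)
        a = shifted_wald_pdf(t, p, tau1 + tau2)
        b = shifted_wald_pdf(t - tau1, p, tau2)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-300)


class TestWaldSample:
    def test_moments_match_law(self, cp_slow):
        n = 100_000
        x = wald_sample(cp_slow, n, seed=5)
        mean, var, _ = wald_moments(cp_slow)
        se_mean = np.sqrt(var / n)
        assert abs(x.mean() - mean) < 3 * se_mean
        # SE of the sample variance via the fourth central moment
        m4 = np.mean((x - x.mean()) ** 4)
        se_var = np.sqrt((m4 - var**2) / n)
        assert abs(x.var() - var) < 3 * se_var

    def test_support_and_reproducibility(self, cp_slow):
        x = wald_sample(cp_slow, 1000, seed=3)
        assert np.all(x > 0)
        np.testing.assert_array_equal(x, wald_sample(cp_slow, 1000, seed=3))

    def test_distribution_by_ks(self, cp_slow):
        x = wald_sample(cp_slow, 5000, seed=17)
        stat = stats.ks_1samp(x, lambda t: wald_cdf(t, cp_slow)).statistic
        assert stat < 1.63 / np.sqrt(5000)  # 1% critical value

    def test_bad_n_rejected(self, cp_slow):
        with pytest.raises(ValueError):
            wald_sample(cp_slow, 0, seed=1)


class TestEMG:
    def test_normalizes_over_reals(self, emg_model):
        total, _ = integrate.quad(
            lambda t: emg_pdf(t, emg_model), -np.inf, np.inf, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mean_is_additive(self, emg_model):
        mean, _ = integrate.quad(
            lambda t: t * emg_pdf(t, emg_model), -np.inf, np.inf, limit=200
        )
        assert mean == pytest.approx(emg_model.gauss_mean + 1 / emg_model.rate, rel=1e-6)

    def test_fast_dwell_limit_is_gaussian(self):
        m = EMGModel(rate=1e4, gauss_mean=10.0, gauss_sd=1.5)
        t = np.linspace(5, 15, 101)
        gauss = stats.norm.pdf(t, loc=10.0, scale=1.5)
        np.testing.assert_allclose(emg_pdf(t, m), gauss, rtol=2e-3)

    @pytest.mark.parametrize("rate,gm,gs", [(0, 10, 1), (-1, 10, 1), (1, 10, 0)])
    def test_invalid_model_rejected(self, rate, gm, gs):
        with pytest.raises(ValueError):
            EMGModel(rate, gm, gs)


class TestLogForm:
    def test_logpdf_is_minus_inf_not_nan_outside_support(self, cp_slow):
        out = wald_logpdf(np.array([-1.0, 0.0, 5.0]), cp_slow)
        assert out[0] == -np.inf and out[1] == -np.inf
        assert np.isfinite(out[2])

    def test_densities_nonnegative(self, cp_slow, emg_model):
        t = np.linspace(-5, 50, 500)
        assert np.all(wald_pdf(t, cp_slow) >= 0)
        assert np.all(emg_pdf(t, emg_model) >= 0)


def test_ddt_model_invariants(cp_slow):
    with pytest.raises(ValueError):
        DDTModel([])
    m = DDTModel([cp_slow, CheckpointParams(0.1, 0.05)])
    assert m.m == 2
    assert m.mean == pytest.approx(5.0 + 10.0)
    assert m.variance == pytest.approx(1.25 + 0.05**2 / 0.1**3)
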
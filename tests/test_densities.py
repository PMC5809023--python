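"""Grid discretization, left-Riemann convolution, and delta substitution."""

import numpy as np
import pytest

from ddtcycle import (
    CheckpointParams,
    DDTModel,
    concentration_check,
    convolve,
    density_at,
    discretize,
    model_density,
    shifted_wald_pdf,
    wald_pdf,
    wald_sample,
)
from ddtcycle.densities import (
    DensityGrid,
    NormalizationWarning,
    TruncationWarning,
)


class TestDiscretize:
    def test_wald_grid_mass(self, cp_slow):
        grid = discretize(lambda t: wald_pdf(t, cp_slow), t_max=30.0, step=0.01)
        assert abs(grid.mass - 1.0) < 1e-4

    def test_underresolved_step_warns(self):
        # std ~0.011 h << step 0.5: the peak cannot be resolved
        cp = CheckpointParams(0.2, 1e-3)
        with pytest.warns(NormalizationWarning):
            discretize(lambda t: wald_pdf(t, cp), t_max=30.0, step=0.5)

    def test_truncating_horizon_warns(self, cp_slow):
        with pytest.warns(TruncationWarning):
            discretize(lambda t: wald_pdf(t, cp_slow), t_max=4.0, step=0.01)

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            discretize(lambda t: np.zeros_like(t), t_max=10.0, step=0.1)

    def test_bad_geometry_rejected(self, cp_slow):
        with pytest.raises(ValueError):
            discretize(lambda t: wald_pdf(t, cp_slow), t_max=0.01, step=0.1)


class TestConvolve:
    def test_identity_element(self, cp_slow):
        grid = discretize(lambda t: wald_pdf(t, cp_slow), t_max=30.0, step=0.01)
        # one-point unit-mass grid at 0: step * value = 1
        unit = DensityGrid(0.0, 0.01, np.array([100.0]))
        out = convolve(grid, unit)
        np.testing.assert_allclose(out.values[: grid.values.size], grid.values, atol=1e-10)

    def test_mean_additivity(self, cp_slow):
        a = discretize(lambda t: wald_pdf(t, cp_slow), t_max=40.0, step=0.01)
        b = discretize(
            lambda t: wald_pdf(t, CheckpointParams(0.1, 0.05)), t_max=40.0, step=0.01
        )
        out = convolve(a, b)
        assert abs(out.mean() - (a.mean() + b.mean())) < 2 * 0.01

    def test_against_monte_carlo_sums(self, cp_slow):
        """CDF of the numerical convolution vs sums of paired exact draws."""
        n = 50_000
        sums = wald_sample(cp_slow, n, seed=21) + wald_sample(cp_slow, n, seed=22)
        a = discretize(lambda t: wald_pdf(t, cp_slow), t_max=40.0, step=0.01)
        out = convolve(a, a)
        grid_cdf = np.cumsum(out.values) * out.step
        ecdf_at_nodes = np.searchsorted(np.sort(sums), out.times, side="right") / n
        assert np.max(np.abs(grid_cdf - ecdf_at_nodes)) < 0.01

    def test_fft_matches_direct_left_riemann(self, cp_slow):
        a = discretize(lambda t: wald_pdf(t, cp_slow), t_max=20.0, step=0.02)
        out = convolve(a, a)
        direct = np.convolve(a.values, a.values) * a.step
        np.testing.assert_allclose(out.values, np.clip(direct, 0, None), atol=1e-10)

    def test_commutative(self, cp_slow):
        a = discretize(lambda t: wald_pdf(t, cp_slow), t_max=25.0, step=0.01)
        b = discretize(
            lambda t: wald_pdf(t, CheckpointParams(0.3, 0.4)), t_max=25.0, step=0.01
        )
        np.testing.assert_allclose(
            convolve(a, b).values, convolve(b, a).values, atol=1e-12
        )

    def test_mismatched_steps_rejected(self, cp_slow):
        a = discretize(lambda t: wald_pdf(t, cp_slow), t_max=20.0, step=0.01)
        b = discretize(lambda t: wald_pdf(t, cp_slow), t_max=20.0, step=0.02)
        with pytest.raises(ValueError):
            convolve(a, b)


class TestConcentrationCheck:
    def test_wide_component_not_substituted(self, cp_slow):
        # std = sqrt(0.01/0.008) ~ 1.118 >> 0.01
        d = concentration_check(cp_slow, step=0.01)
        assert not d.substitute
        assert d.width == pytest.approx(1.1180339887)

    def test_narrow_component_substituted_at_mean(self):
        cp = CheckpointParams(0.2, 1e-4)
        d = concentration_check(cp, step=0.01)
        assert d.substitute
        assert d.delta.location == pytest.approx(5.0)
        assert d.width == pytest.approx(1.118e-3, rel=1e-3)

    def test_vanishing_sigma_always_substituted(self):
        for sigma in (1e-6, 1e-9, 1e-12):
            d = concentration_check(CheckpointParams(0.2, sigma), step=0.01)
            assert d.substitute

    def test_bad_step_rejected(self, cp_slow):
        with pytest.raises(ValueError):
            concentration_check(cp_slow, step=0.0)


class TestModelDensity:
    def test_single_checkpoint_equals_discretized_wald(self, cp_slow):
        grid, report = model_density(DDTModel([cp_slow]), t_max=30.0, step=0.01)
        ref = discretize(lambda t: wald_pdf(t, cp_slow), t_max=30.0, step=0.01)
        np.testing.assert_allclose(grid.values, ref.values, rtol=1e-12)
        assert not report.any_substituted

    def test_concentrated_component_becomes_translation(self, cp_slow):
        """A near-deterministic component (mean 3.5) acts as a pure 3.5 h shift."""
        narrow = CheckpointParams(1.0 / 3.5, 1e-5)
        model = DDTModel([cp_slow, narrow])
        grid, report = model_density(model, t_max=40.0, step=0.01)
        assert report.substituted == (1,)
        assert report.tau_total == pytest.approx(3.5)
        t = grid.times
        expected = shifted_wald_pdf(t, cp_slow, 3.5)
        err = np.max(np.abs(grid.values - expected))
        # discrepancy dominated by the shift interpolation, bounded by the report
        assert err <= max(report.error_bound, 1e-3)

    def test_mass_near_one_when_resolved(self, ddt2_hl):
        grid, _ = model_density(ddt2_hl, t_max=120.0, step=0.01)
        assert abs(grid.mass - 1.0) < 1e-3

    def test_all_substitutable_is_degenerate(self):
        model = DDTModel([CheckpointParams(0.2, 1e-5), CheckpointParams(0.5, 1e-5)])
        with pytest.raises(ValueError, match="point-mass"):
            model_density(model, t_max=20.0, step=0.01)

    def test_moment_additivity(self):
        """Grid mean and variance match the sums over independent checkpoints."""
        model = DDTModel(
            [CheckpointParams(0.25, 0.3), CheckpointParams(0.5, 0.2),
             CheckpointParams(1.0, 0.4)]
        )
        grid, _ = model_density(model, t_max=60.0, step=0.01)
        assert abs(grid.mean() - model.mean) < 2 * 0.01
        assert grid.variance() == pytest.approx(model.variance, rel=0.02)

    def test_substitution_consistent_with_fine_grid_convolution(self, cp_slow):
        """As the unsubstituted convolution is refined it approaches the
        delta-substituted result, within the reported bound."""
        narrow = CheckpointParams(1.0 / 3.5, 2.3e-3)  # std ~0.015 h
        model = DDTModel([cp_slow, narrow])
        coarse, report = model_density(model, t_max=30.0, step=0.01)
        assert report.substituted == (1,)
        errs = []
        for fine_step in (0.002, 0.001):
            a = discretize(lambda t: wald_pdf(t, cp_slow), 30.0, fine_step)
            b = discretize(lambda t: wald_pdf(t, narrow), 30.0, fine_step)
            full = convolve(a, b)
            at_coarse = density_at(full, coarse.times)
            errs.append(np.max(np.abs(at_coarse - coarse.values)))
        assert errs[1] <= errs[0] + 1e-9  # refinement does not worsen agreement
        assert errs[1] <= report.error_bound + 0.02 * np.max(coarse.values)


class TestDensityAt:
    def test_on_node_off_node_and_outside(self, cp_slow):
        grid = discretize(lambda t: wald_pdf(t, cp_slow), t_max=20.0, step=0.1)
        assert density_at(grid, 5.0) == pytest.approx(grid.values[50])
        v = density_at(grid, 5.05)
        assert min(grid.values[50], grid.values[51]) <= v <= max(
            grid.values[50], grid.values[51]
        )
        assert density_at(grid, 25.0) == 0.0
        assert density_at(grid, -1.0) == 0.0
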
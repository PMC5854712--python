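"""Unit and property tests for the MFDFA machinery.

Brute-force oracles (dense per-window OLS, naive generalized means) are
implemented here independently of the package code paths they check.
"""

import numpy as np
import pytest

from songfractal.mfdfa import (HQSpectrum, default_q_grid, default_scales,
                               hurst_spectrum, integrate_profile,
                               q_fluctuation, spectrum_width,
                               windowed_residuals)


def naive_windowed_f2(y, s):
    """Independent per-window OLS residual oracle (loops + polyfit)."""
    n = len(y)
    n_s = n // s
    out = []
    t = np.arange(s)
    for v in range(n_s):
        seg = y[v * s:(v + 1) * s]
        coef = np.polyfit(t, seg, 1)
        out.append(np.mean((seg - np.polyval(coef, t)) ** 2))
    for v in range(n_s):
        seg = y[n - (v + 1) * s: n - v * s][::-1]  # windows tiled from the end
        coef = np.polyfit(t, seg, 1)
        out.append(np.mean((seg - np.polyval(coef, t)) ** 2))
    return np.array(out)


class TestIntegrateProfile:
    def test_constant_series_gives_zero_profile(self):
        np.testing.assert_array_equal(integrate_profile([3.0, 3.0, 3.0]).values,
                                      np.zeros(3))

    def test_hand_computed_profile(self):
        np.testing.assert_allclose(integrate_profile([1.0, 2.0, 3.0]).values,
                                   [-1.0, -1.0, 0.0], atol=1e-12)

    def test_profile_ends_at_zero(self, rng):
        x = rng.normal(size=500)
        y = integrate_profile(x).values
        assert abs(y[-1]) < 1e-9 * 500 * np.std(x)

    @pytest.mark.parametrize("bad", [[], [1.0], [1.0, np.nan, 2.0]])
    def test_rejects_degenerate_input(self, bad):
        with pytest.raises(ValueError):
            integrate_profile(bad)


class TestWindowedResiduals:
    def test_linear_profile_has_zero_residuals(self):
        y = integrate_profile(np.arange(100.0))  # any profile...
        lin = np.linspace(-3.0, 7.0, 100)
        f2 = windowed_residuals(lin, 10)
        np.testing.assert_allclose(f2, 0.0, atol=1e-20)
        assert f2.size == 2 * 10

    def test_exact_multiple_passes_coincide(self, rng):
        y = rng.normal(size=80).cumsum()
        f2 = windowed_residuals(y, 10)
        fwd, bwd = f2[:8], f2[8:]
        # N a multiple of s: both passes tile identically (up to order)
        np.testing.assert_allclose(np.sort(fwd), np.sort(bwd), rtol=1e-12)

    def test_matches_bruteforce_ols_oracle(self, rng):
        y = rng.normal(size=40).cumsum()
        f2 = windowed_residuals(y, 10)
        oracle = naive_windowed_f2(y, 10)
        # backward-pass orientation differs; compare as multisets per pass
        np.testing.assert_allclose(np.sort(f2[:4]), np.sort(oracle[:4]),
                                   atol=1e-10)
        np.testing.assert_allclose(np.sort(f2[4:]), np.sort(oracle[4:]),
                                   atol=1e-10)

    @pytest.mark.parametrize("s", [5, 9, 26, 500])
    def test_scale_bounds_enforced(self, s, rng):
        y = rng.normal(size=100).cumsum()
        with pytest.raises(ValueError):
            windowed_residuals(y, s)


class TestQFluctuation:
    def test_constant_f2_gives_sqrt_for_all_q(self):
        f2 = np.full(12, 0.49)
        for q in [0.1, 0.5, 2.0, 5.0]:
            assert q_fluctuation(f2, q) == pytest.approx(0.7, rel=1e-12)

    def test_q2_is_plain_rms(self, rng):
        f2 = rng.uniform(0.1, 2.0, 30)
        assert q_fluctuation(f2, 2.0) == pytest.approx(
            np.sqrt(np.mean(f2)), rel=1e-12)

    def test_power_mean_monotone_in_q(self, rng):
        f2 = rng.uniform(0.01, 5.0, 25)
        values = [q_fluctuation(f2, q) for q in (0.5, 2.0, 5.0)]
        assert values[0] <= values[1] <= values[2]

    def test_zero_windows_are_well_defined(self):
        f2 = np.array([0.0, 0.0, 1.0, 4.0])
        for q in (0.5, 2.0, 5.0):
            expected = (np.mean(f2 ** (q / 2))) ** (1 / q)
            assert q_fluctuation(f2, q) == pytest.approx(expected, rel=1e-12)


class TestHurstSpectrum:
    def test_white_noise_scaling_exponent_near_half(self):
        from songfractal.simulate import gen_white_noise
        hs = [hurst_spectrum(gen_white_noise(4000, seed), qs=[2.0]).h[0]
              for seed in range(10)]
        assert 0.40 < np.mean(hs) < 0.60

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            hurst_spectrum(np.full(200, 2.5))

    def test_exact_zero_residual_windows_are_handled(self):
        # piecewise-constant series: windows away from the step have a
        # perfectly linear profile (F2 = 0 exactly); the q-order means
        # must absorb those zeros without error
        x = np.concatenate([np.zeros(200), np.ones(200)])
        spec = hurst_spectrum(x, qs=[0.5, 2.0, 5.0], scales=[10, 20, 50, 100])
        assert np.all(np.isfinite(spec.h))

    def test_fit_diagnostics_shape_and_quality(self, rng):
        x = rng.normal(size=2000)
        spec = hurst_spectrum(x)
        assert spec.q.shape == spec.h.shape == spec.r2.shape
        assert spec.width >= 0
        assert np.all(spec.r2[spec.q >= 1.0] > 0.9)


class TestSpectrumWidth:
    def test_constant_h_zero_width(self):
        spec = HQSpectrum(q=np.array([1.0, 2.0]), h=np.array([0.5, 0.5]),
                          intercepts=np.zeros(2), r2=np.ones(2))
        assert spectrum_width(spec) == 0.0

    def test_hand_computed_width(self):
        spec = HQSpectrum(q=np.array([1.0, 2.0, 3.0]),
                          h=np.array([0.9, 0.7, 0.6]),
                          intercepts=np.zeros(3), r2=np.ones(3))
        assert spectrum_width(spec) == pytest.approx(0.3)

    def test_single_q_rejected(self):
        spec = HQSpectrum(q=np.array([2.0]), h=np.array([0.5]),
                          intercepts=np.zeros(1), r2=np.ones(1))
        with pytest.raises(ValueError):
            spectrum_width(spec)


class TestGrids:
    def test_scale_grid_respects_bounds(self):
        s = default_scales(4000)
        assert s[0] >= 10 and s[-1] <= 1000
        assert np.all(np.diff(s) > 0)

    def test_scale_grid_rejects_short_series(self):
        with pytest.raises(ValueError):
            default_scales(30)

    def test_q_grid_default_range(self):
        q = default_q_grid()
        assert q[0] == pytest.approx(0.1)
        assert q[-1] == pytest.approx(5.0)
        assert q.size == 50


def test_cascade_h_monotone_in_q():
    """h(q) decreases with q for multiplicative cascades (fit noise <=0.02)."""
    from songfractal.simulate import CascadeSpec, gen_binomial_cascade
    x = gen_binomial_cascade(CascadeSpec(p=0.7, levels=12, seed=5))
    spec = hurst_spectrum(x, qs=np.arange(0.5, 5.01, 0.25))
    assert np.all(np.diff(spec.h) <= 0.02)
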
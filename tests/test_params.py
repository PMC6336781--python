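"""Parameter maps: spectra, ALFF/fALFF, Kendall's W / ReHo, degree
centrality, normalization and smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from restmvpa.params import (
    FcsSpec,
    SmoothSpec,
    alff_map,
    amplitude_spectrum,
    falff_map,
    fcs_map,
    finalize_map,
    gaussian_smooth,
    kendalls_w,
    normalize_by_mask_mean,
    reho_map,
    zscore_map,
)
from restmvpa.preproc import BandSpec
from restmvpa.types import BoldRun, ParameterMap


def _bold(data, tr=2.0, state="regressed"):
    data = np.asarray(data, dtype=float)
    return BoldRun(data=data, voxel_size_mm=3.0, tr_s=tr,
                   brain_mask=np.ones(data.shape[:3], bool), state=state)


def _pmap(values, kind="alff", state="raw", mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, bool)
    return ParameterMap(values=values, kind=kind, state=state, mask=mask)


class TestAmplitudeSpectrum:
    def test_on_bin_sinusoid_concentrates_in_its_bin(self):
        n, tr, f = 200, 2.0, 0.05
        t = np.arange(n) * tr
        a = 3.0
        freqs, amp = amplitude_spectrum(a * np.sin(2 * np.pi * f * t), tr)
        k = np.argmin(np.abs(freqs - f))
        others = np.delete(amp, k)
        assert others.max() < 1e-10 * a
        assert amp[k] > 0

    def test_constant_series_all_zero(self):
        _, amp = amplitude_spectrum(np.full(50, 4.2), 2.0)
        assert np.abs(amp).max() < 1e-10

    def test_linearity_in_input_scale(self, rng):
        x = rng.standard_normal(100)
        _, a1 = amplitude_spectrum(x, 2.0)
        _, a2 = amplitude_spectrum(2 * x, 2.0)
        np.testing.assert_allclose(a2, 2 * a1, atol=1e-12)


class TestAlffFalff:
    def test_alff_ratio_tracks_sinusoid_amplitudes(self, band_2s):
        t = np.arange(190) * 2.0
        sig = np.sin(2 * np.pi * 0.05 * t)
        data = np.zeros((1, 1, 2, 190))
        data[0, 0, 0] = sig
        data[0, 0, 1] = 2 * sig
        bold = _bold(data)
        amap = alff_map(bold, bold.brain_mask, band_2s)
        assert amap.values[0, 0, 1] / amap.values[0, 0, 0] == pytest.approx(2.0, abs=1e-9)
        assert amap.kind == "alff" and amap.state == "raw"

    def test_flat_voxel_zero_noise_voxel_positive(self, band_2s, rng):
        data = np.zeros((1, 1, 2, 100))
        data[0, 0, 1] = rng.standard_normal(100)
        amap = alff_map(_bold(data), np.ones((1, 1, 2), bool), band_2s)
        assert amap.values[0, 0, 0] == 0
        assert amap.values[0, 0, 1] > 0

    def test_falff_one_for_pure_in_band(self, band_2s):
        t = np.arange(190) * 2.0
        data = np.sin(2 * np.pi * 0.05 * t).reshape(1, 1, 1, -1)
        fmap = falff_map(_bold(data), np.ones((1, 1, 1), bool), band_2s)
        assert fmap.values[0, 0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_falff_zero_for_pure_out_of_band(self, band_2s):
        t = np.arange(190) * 2.0
        data = np.sin(2 * np.pi * 0.2 * t).reshape(1, 1, 1, -1)
        fmap = falff_map(_bold(data), np.ones((1, 1, 1), bool), band_2s)
        assert fmap.values[0, 0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_falff_bounded_and_white_noise_near_band_fraction(self, band_2s, rng):
        n = 2000  # long series -> flat expected spectrum
        data = rng.standard_normal((2, 2, 2, n))
        fmap = falff_map(_bold(data), np.ones((2, 2, 2), bool), band_2s)
        vals = fmap.in_mask()
        assert np.all(vals >= 0) and np.all(vals <= 1)
        freqs = np.fft.rfftfreq(n, 2.0)[1:]
        frac = ((freqs >= 0.01 - 1e-12) & (freqs <= 0.08 + 1e-12)).mean()
        assert np.mean(vals) == pytest.approx(frac, rel=0.15)

    def test_bandpassed_input_rejected(self, band_2s, rng):
        bold = _bold(rng.standard_normal((1, 1, 1, 50)), state="bandpassed")
        with pytest.raises(ValueError):
            alff_map(bold, bold.brain_mask, band_2s)
        with pytest.raises(ValueError):
            falff_map(bold, bold.brain_mask, band_2s)


class TestKendallsW:
    def test_identical_series_give_one(self):
        x = np.tile(np.array([3.0, 1.0, 2.0, 5.0]), (4, 1))
        assert kendalls_w(x) == pytest.approx(1.0, abs=1e-12)

    def test_reversed_ranks_give_zero(self):
        assert kendalls_w(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])) == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_series_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert kendalls_w(np.full((3, 5), 2.0)) == 0.0

    def test_matches_mean_pairwise_spearman_oracle(self, rng):
        """W == ((m-1)*mean pairwise Spearman + 1)/m on random instances."""
        for _ in range(200):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(3, 9))
            x = rng.standard_normal((m, n))
            rho = np.mean([spearmanr(x[i], x[j]).statistic
                           for i in range(m) for j in range(i + 1, m)])
            oracle = ((m - 1) * rho + 1.0) / m
            assert abs(kendalls_w(x) - oracle) < 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 6), st.integers(3, 10), st.integers(0, 10_000))
    def test_bounded_and_monotone_invariant(self, m, n, seed):
        """W in [0,1] and invariant under common strictly monotone maps."""
        x = np.random.default_rng(seed).standard_normal((m, n))
        w = kendalls_w(x)
        assert -1e-12 <= w <= 1 + 1e-12
        assert kendalls_w(np.exp(x)) == pytest.approx(w, abs=1e-12)
        assert kendalls_w(3 * x + 7) == pytest.approx(w, abs=1e-12)


class TestReho:
    def test_uniform_field_gives_w_one_in_interior(self, rng):
        series = rng.standard_normal(40)
        data = np.tile(series, (6, 6, 6, 1))
        bold = _bold(data, state="bandpassed")
        rmap = reho_map(bold, np.ones((6, 6, 6), bool))
        assert rmap.values[1:-1, 1:-1, 1:-1] == pytest.approx(1.0, abs=1e-9)
        assert rmap.values[0, 0, 0] == pytest.approx(1.0, abs=1e-9)  # 8 series, all equal

    def test_independent_noise_has_low_mean_w(self, rng):
        data = rng.standard_normal((8, 8, 8, 190))
        rmap = reho_map(_bold(data, state="bandpassed"), np.ones((8, 8, 8), bool))
        assert rmap.in_mask().mean() < 0.2

    def test_corner_voxel_uses_eight_series(self, rng):
        """A corner neighborhood (8 voxels) of identical series is still
        perfectly concordant, a mixed one is not."""
        data = rng.standard_normal((4, 4, 4, 30))
        data[:2, :2, :2] = data[0, 0, 0]  # corner 2x2x2 block identical
        rmap = reho_map(_bold(data, state="bandpassed"), np.ones((4, 4, 4), bool))
        assert rmap.values[0, 0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_mask_restricts_neighbors(self, rng):
        data = rng.standard_normal((4, 4, 4, 30))
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True  # no usable neighbors -> m < 2 -> 0
        rmap = reho_map(_bold(data, state="bandpassed"), mask)
        assert rmap.values[0, 0, 0] == 0.0

    def test_unfiltered_input_rejected(self, rng):
        bold = _bold(rng.standard_normal((3, 3, 3, 20)), state="regressed")
        with pytest.raises(ValueError):
            reho_map(bold, np.ones((3, 3, 3), bool))


class TestFcs:
    def test_analytic_three_voxel_example(self, rng):
        """r(A,B)=0.5 counts toward FCS(A); r(A,C)=0.1 is sub-threshold."""
        n = 20000
        z = rng.standard_normal((3, n))
        a = (z[0] - z[0].mean()) / z[0].std()

        def unit_resid(v):
            v = v - v.mean()
            v -= (v @ a / n) * a
            return v / v.std()

        b = 0.5 * a + np.sqrt(0.75) * unit_resid(z[1])
        c = 0.1 * a + np.sqrt(0.99) * unit_resid(z[2])
        data = np.stack([a, b, c])[None, None, :, :]
        bold = _bold(data, state="bandpassed")
        fmap = fcs_map(bold, np.ones((1, 1, 3), bool))
        assert fmap.values[0, 0, 0] == pytest.approx(np.arctanh(0.5), abs=1e-9)

    def test_independent_noise_gives_near_zero_fcs(self, rng):
        data = rng.standard_normal((4, 4, 4, 400))
        fmap = fcs_map(_bold(data, state="bandpassed"), np.ones((4, 4, 4), bool))
        # null correlations rarely exceed 0.2 at n=400
        assert np.abs(fmap.in_mask()).mean() < 0.05

    def test_identical_voxels_clipped_to_finite(self, rng):
        series = rng.standard_normal(50)
        data = np.stack([series, series])[None, None, :, :]
        fmap = fcs_map(_bold(data, state="bandpassed"), np.ones((1, 1, 2), bool))
        expected = np.arctanh(1.0 - 1e-7)
        assert fmap.values[0, 0, 0] == pytest.approx(expected, rel=1e-6)
        assert np.all(np.isfinite(fmap.values))

    def test_scale_invariance(self, rng):
        data = rng.standard_normal((3, 3, 3, 100))
        bold = _bold(data, state="bandpassed")
        scaled = _bold(data * rng.uniform(0.5, 5.0, (3, 3, 3, 1)), state="bandpassed")
        mask = np.ones((3, 3, 3), bool)
        np.testing.assert_allclose(fcs_map(bold, mask).values,
                                   fcs_map(scaled, mask).values, atol=1e-9)

    def test_zero_variance_voxel_gets_zero(self, rng):
        data = rng.standard_normal((1, 1, 3, 60))
        data[0, 0, 1] = 5.0
        fmap = fcs_map(_bold(data, state="bandpassed"), np.ones((1, 1, 3), bool))
        assert fmap.values[0, 0, 1] == 0.0


class TestNormalization:
    def test_mask_mean_normalization_examples(self):
        pmap = _pmap(np.array([2.0, 4.0]).reshape(1, 1, 2))
        out = normalize_by_mask_mean(pmap)
        np.testing.assert_allclose(out.values.ravel(), [2 / 3, 4 / 3])
        assert out.state == "normalized"
        assert out.in_mask().mean() == pytest.approx(1.0, abs=1e-12)

    def test_constant_map_becomes_ones(self):
        out = normalize_by_mask_mean(_pmap(np.full((2, 2, 2), 3.7)))
        np.testing.assert_allclose(out.values, 1.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            normalize_by_mask_mean(_pmap(np.zeros((2, 2, 2))))

    def test_zscore_two_voxel_population_sd(self):
        out = zscore_map(_pmap(np.array([1.0, 3.0]).reshape(1, 1, 2), kind="fcs"))
        np.testing.assert_allclose(out.values.ravel(), [-1.0, 1.0])
        assert out.in_mask().mean() == pytest.approx(0.0, abs=1e-12)
        assert out.in_mask().std() == pytest.approx(1.0, abs=1e-12)

    def test_zscore_constant_map_rejected(self):
        with pytest.raises(ValueError):
            zscore_map(_pmap(np.full((2, 2, 2), 1.0), kind="fcs"))


class TestSmoothing:
    def test_sigma_conversion(self):
        spec = SmoothSpec(fwhm_mm=8.0, voxel_size_mm=3.0)
        assert spec.sigma_voxels == pytest.approx(8 / 3 / 2.35482, abs=1e-4)

    def test_constant_map_unchanged_in_interior(self):
        pmap = _pmap(np.full((16, 16, 16), 2.5))
        out = gaussian_smooth(pmap, SmoothSpec(fwhm_mm=6.0, voxel_size_mm=3.0))
        np.testing.assert_allclose(out.values[6:-6, 6:-6, 6:-6], 2.5, atol=1e-6)
        assert out.state == "smoothed"

    def test_impulse_mass_preserved(self):
        vals = np.zeros((21, 21, 21))
        vals[10, 10, 10] = 1.0
        out = gaussian_smooth(_pmap(vals), SmoothSpec(fwhm_mm=8.0, voxel_size_mm=3.0))
        assert out.values.sum() == pytest.approx(1.0, abs=1e-6)


class TestChains:
    def test_finalize_orders(self, rng):
        raw = _pmap(np.abs(rng.standard_normal((6, 6, 6))) + 0.5)
        out = finalize_map(raw, SmoothSpec(voxel_size_mm=3.0))
        assert out.state == "smoothed"
        fcs_raw = _pmap(rng.standard_normal((6, 6, 6)), kind="fcs")
        out2 = finalize_map(fcs_raw, SmoothSpec(voxel_size_mm=3.0))
        # z-scored after smoothing: mean 0 / SD 1 in mask
        assert out2.in_mask().mean() == pytest.approx(0.0, abs=1e-9)
        assert out2.in_mask().std() == pytest.approx(1.0, abs=1e-9)

    def test_finalize_rejects_non_raw(self, rng):
        pmap = _pmap(np.abs(rng.standard_normal((4, 4, 4))) + 1, state="normalized")
        with pytest.raises(ValueError):
            finalize_map(pmap, SmoothSpec())
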
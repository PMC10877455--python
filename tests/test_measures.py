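"""fALFF / LCOR / GCOR / relative GMV / smoothing against independent oracles."""

import numpy as np
import pytest

from depstrat.core import BandSpec, MeasureMap, VolumeGrid
from depstrat.measures import (
    compute_falff,
    compute_gcor,
    compute_lcor,
    compute_relative_gmv,
    smooth_map,
)

BAND = BandSpec(0.008, 0.09)
TR = 0.735


def _ts_volume(grid, series):
    """Broadcast one time series to every voxel of a grid."""
    out = np.zeros(tuple(grid.shape) + (len(series),))
    out[grid.mask] = series
    return out


class TestFalff:
    def test_in_band_sinusoid_concentrates_amplitude(self, grid5):
        t = np.arange(120) * TR
        vol = _ts_volume(grid5, np.sin(2 * np.pi * 0.05 * t))
        m = compute_falff(vol, BAND, TR, grid5)
        assert (m.values[grid5.mask] >= 0.95).all()

    def test_out_of_band_sinusoid_excluded(self, grid5):
        t = np.arange(120) * TR
        vol = _ts_volume(grid5, np.sin(2 * np.pi * 0.30 * t))
        m = compute_falff(vol, BAND, TR, grid5)
        assert (m.values[grid5.mask] <= 0.05).all()

    def test_white_noise_mean_matches_band_bin_fraction(self, rng):
        # bin-count oracle: iid spectra make the expected ratio the share of
        # positive-frequency bins falling inside the band
        grid = VolumeGrid.full((12, 12, 12))
        T = 120
        vol = rng.standard_normal(tuple(grid.shape) + (T,))
        m = compute_falff(vol, BAND, TR, grid)
        freqs = np.fft.rfftfreq(T, d=TR)
        pos = freqs > 0
        frac = ((freqs >= BAND.low) & (freqs <= BAND.high) & pos).sum() / pos.sum()
        assert abs(m.values[grid.mask].mean() - frac) < 0.01

    def test_invariant_to_positive_scaling(self, grid5, rng):
        vol = rng.standard_normal(tuple(grid5.shape) + (64,))
        scale = rng.uniform(0.1, 10, tuple(grid5.shape))[..., None]
        a = compute_falff(vol, BAND, TR, grid5)
        b = compute_falff(vol * scale, BAND, TR, grid5)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_constant_series_yields_zero(self, grid5):
        vol = np.ones(tuple(grid5.shape) + (64,))
        m = compute_falff(vol, BAND, TR, grid5)
        assert (m.values == 0).all()

    def test_values_in_unit_interval(self, grid5, rng):
        vol = rng.standard_normal(tuple(grid5.shape) + (64,))
        v = compute_falff(vol, BAND, TR, grid5).values[grid5.mask]
        assert (v >= 0).all() and (v <= 1).all()

    def test_detrend_matches_scipy_reference(self, rng):
        from scipy import signal

        from depstrat.measures import _detrend_linear

        data = rng.standard_normal((40, 90)) + np.linspace(0, 3, 90)
        np.testing.assert_allclose(
            _detrend_linear(data),
            signal.detrend(data, axis=1, type="linear"),
            atol=1e-10,
        )

    def test_too_few_timepoints_rejected(self, grid5, rng):
        with pytest.raises(ValueError):
            compute_falff(
                rng.standard_normal(tuple(grid5.shape) + (16,)), BAND, TR, grid5
            )


class TestLcor:
    def test_identical_series_everywhere_gives_one(self, grid5):
        series = np.sin(np.arange(64))
        m = compute_lcor(_ts_volume(grid5, series), grid5, kernel_fwhm=10.0)
        np.testing.assert_allclose(m.values[grid5.mask], 1.0, atol=1e-10)

    def test_independent_noise_correlations_vanish(self, rng):
        grid = VolumeGrid.full((8, 8, 8))
        T = 400
        vol = rng.standard_normal(tuple(grid.shape) + (T,))
        m = compute_lcor(vol, grid, kernel_fwhm=10.0)
        assert abs(m.values[grid.mask].mean()) < 3.0 / np.sqrt(T)

    def test_interleaved_anticorrelated_populations_negative(self, grid5, rng):
        # checkerboard of +s(t)/-s(t): nearest neighbors dominate a narrow
        # kernel, so the weighted neighbor correlation is negative everywhere
        s = rng.standard_normal(64)
        ii, jj, kk = np.indices(grid5.shape)
        sign = np.where((ii + jj + kk) % 2 == 0, 1.0, -1.0)
        vol = sign[..., None] * s[None, None, None, :]
        m = compute_lcor(vol, grid5, kernel_fwhm=4.0)
        assert (m.values[grid5.mask] < 0).all()

    def test_single_voxel_mask_rejected(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        grid = VolumeGrid((5, 5, 5), (4.0, 4.0, 4.0), mask)
        with pytest.raises(ValueError):
            compute_lcor(np.zeros((5, 5, 5, 64)), grid)

    def test_invariant_to_voxelwise_affine_rescale(self, grid5, rng):
        vol = rng.standard_normal(tuple(grid5.shape) + (64,))
        slope = rng.uniform(0.5, 2.0, tuple(grid5.shape))[..., None]
        offset = rng.normal(0, 5, tuple(grid5.shape))[..., None]
        a = compute_lcor(vol, grid5, kernel_fwhm=8.0)
        b = compute_lcor(vol * slope + offset, grid5, kernel_fwhm=8.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


def gcor_bruteforce(vol, grid):
    """O(V^2) oracle: mean off-diagonal Pearson correlation per voxel."""
    data = vol[grid.mask]
    r = np.corrcoef(data)
    np.fill_diagonal(r, 0.0)
    return r.sum(axis=1) / (data.shape[0] - 1)


class TestGcor:
    def test_identical_series_gives_one(self, grid5):
        m = compute_gcor(_ts_volume(grid5, np.cos(np.arange(64))), grid5)
        np.testing.assert_allclose(m.values[grid5.mask], 1.0, atol=1e-10)

    def test_fast_path_equals_bruteforce_oracle(self, grid5, rng):
        vol = rng.standard_normal(tuple(grid5.shape) + (48,))
        fast = compute_gcor(vol, grid5).values[grid5.mask]
        np.testing.assert_allclose(fast, gcor_bruteforce(vol, grid5), atol=1e-10)

    def test_half_anticorrelated_closed_form(self):
        # V/2 voxels +s(t), V/2 voxels -s(t): each voxel correlates +1 with
        # (V/2 - 1) voxels and -1 with V/2, so GCOR = -1/(V-1)
        grid = VolumeGrid.full((4, 4, 4))
        V = grid.n_voxels
        s = np.sin(np.arange(64) * 0.3)
        flat_sign = np.array([1.0, -1.0] * (V // 2))
        vol = np.zeros(tuple(grid.shape) + (64,))
        vol[grid.mask] = flat_sign[:, None] * s[None, :]
        m = compute_gcor(vol, grid)
        np.testing.assert_allclose(m.values[grid.mask], -1.0 / (V - 1), atol=1e-10)

    def test_invariant_to_voxelwise_affine_rescale(self, grid5, rng):
        vol = rng.standard_normal(tuple(grid5.shape) + (48,))
        slope = rng.uniform(0.5, 2.0, tuple(grid5.shape))[..., None]
        a = compute_gcor(vol, grid5)
        b = compute_gcor(vol * slope + 3.0, grid5)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


class TestRelativeGmv:
    def test_direct_ratio(self):
        grid = VolumeGrid.full((10, 10, 10), voxel_size=(10.0, 10.0, 10.0))
        gm = np.full(grid.shape, 0.7)  # 1 mL voxels -> 700 mL total
        ratio, _ = compute_relative_gmv(gm, 1400.0, grid)
        assert ratio == pytest.approx(0.5)

    def test_zero_map_gives_zero(self, grid5):
        ratio, _ = compute_relative_gmv(np.zeros(grid5.shape), 1400.0, grid5)
        assert ratio == 0.0

    def test_matches_summation_oracle(self, grid5, rng):
        gm = rng.uniform(0, 1, grid5.shape)
        tiv = 1500.0
        ratio, m = compute_relative_gmv(gm, tiv, grid5)
        total = 0.0
        for idx in np.argwhere(grid5.mask):
            total += gm[tuple(idx)]
        expected = total * grid5.voxel_volume_ml / tiv
        assert ratio == pytest.approx(expected, abs=1e-12)
        np.testing.assert_array_equal(m.values, gm)

    def test_nonpositive_tiv_rejected(self, grid5):
        with pytest.raises(ValueError):
            compute_relative_gmv(np.ones(grid5.shape), 0.0, grid5)


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, grid8, rng):
        m = MeasureMap("gmv", "s", grid8, rng.standard_normal(grid8.shape))
        out = smooth_map(m, 0.0, grid8)
        np.testing.assert_array_equal(out.values, m.values)

    def test_constant_image_unchanged(self, grid8):
        m = MeasureMap("gmv", "s", grid8, np.full(grid8.shape, 3.5))
        out = smooth_map(m, 8.0, grid8)
        np.testing.assert_allclose(out.values[grid8.mask], 3.5, atol=1e-10)

    def test_delta_kernel_width_matches_fwhm(self):
        # kernel-width oracle: voxels at half maximum span ~FWHM in mm
        grid = VolumeGrid.full((21, 21, 21), voxel_size=(2.0, 2.0, 2.0))
        vals = np.zeros(grid.shape)
        vals[10, 10, 10] = 1.0
        out = smooth_map(MeasureMap("gmv", "s", grid, vals), 8.0, grid).values
        line = out[:, 10, 10]
        above = np.flatnonzero(line >= line.max() / 2.0)
        width_vox = above[-1] - above[0] + 1
        assert abs(width_vox - 8.0 / 2.0) <= 1

    def test_interior_mass_preserved(self):
        grid = VolumeGrid.full((25, 25, 25))
        vals = np.zeros(grid.shape)
        vals[12, 12, 12] = 1.0
        out = smooth_map(MeasureMap("gmv", "s", grid, vals), 8.0, grid).values
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_negative_fwhm_rejected(self, grid8):
        m = MeasureMap("gmv", "s", grid8, np.zeros(grid8.shape))
        with pytest.raises(ValueError):
            smooth_map(m, -1.0, grid8)
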
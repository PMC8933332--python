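"""Voxel metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from netstab import (
    BoldSeries,
    MetricMap,
    SmoothingSpec,
    alff,
    dc,
    falff,
    reho,
    smooth_map,
    zscore_map,
)
from conftest import on_bin_freq, tone


def kendall_w_oracle(series_list):
    """Textbook Kendall's coefficient of concordance over K rank columns."""
    ranks = np.array([stats.rankdata(s) for s in series_list])
    k, n = ranks.shape
    rank_sums = ranks.sum(axis=0)
    s = ((rank_sums - k * (n + 1) / 2.0) ** 2).sum()
    return 12.0 * s / (k**2 * (n**3 - n))


def brute_reho(data, mask, neighborhood=27):
    """Per-voxel Kendall W by explicit neighbour gathering."""
    out = np.full(mask.shape, np.nan)
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
    ]
    for idx in np.argwhere(mask):
        cluster = []
        for off in offsets:
            p = idx + off
            if np.all(p >= 0) and np.all(p < mask.shape) and mask[tuple(p)]:
                cluster.append(data[tuple(p)])
        if len(cluster) >= 2:
            out[tuple(idx)] = kendall_w_oracle(cluster)
    return out


def brute_dc(data, mask, r_threshold=0.25):
    """O(N^2) correlation counting."""
    vox = data[mask]
    n = vox.shape[0]
    counts = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = np.corrcoef(vox[i], vox[j])[0, 1]
            if r > r_threshold:
                counts[i] += 1
                counts[j] += 1
    out = np.full(mask.shape, np.nan)
    out[mask] = counts
    return out


def single_voxel_series(x):
    return BoldSeries(np.asarray(x).reshape(1, 1, 1, -1), 3.0)


ONE_VOXEL_MASK = np.ones((1, 1, 1), dtype=bool)


class TestAlff:
    def test_pure_tone_amplitude_recovered(self):
        n, tr, amp = 290, 3.0, 2.0
        f = on_bin_freq(0.05, n, tr)
        m = alff(single_voxel_series(tone(f, n, tr, amplitude=amp)), ONE_VOXEL_MASK)
        assert m.values[0, 0, 0] == pytest.approx(amp, abs=1e-6)

    def test_linearity_in_signal_scale(self, rng):
        data = rng.normal(size=(2, 2, 1, 64))
        mask = np.ones((2, 2, 1), dtype=bool)
        base = alff(BoldSeries(data, 3.0), mask)
        doubled = alff(BoldSeries(2 * data, 3.0), mask)
        np.testing.assert_allclose(doubled.values, 2 * base.values, rtol=1e-12)

    def test_constant_series_has_zero_amplitude(self):
        m = alff(single_voxel_series(np.full(64, 7.0)), ONE_VOXEL_MASK)
        assert m.values[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_out_of_mask_voxels_carry_sentinel(self, rng):
        mask = np.zeros((2, 1, 1), dtype=bool)
        mask[0] = True
        m = alff(BoldSeries(rng.normal(size=(2, 1, 1, 64)), 3.0), mask)
        assert np.isnan(m.values[1, 0, 0]) and np.isfinite(m.values[0, 0, 0])

    def test_no_band_bin_rejected(self, rng):
        # 32 frames at TR 0.1 s: bin spacing 0.3125 Hz, nothing inside 0.01-0.1
        series = BoldSeries(rng.normal(size=(1, 1, 1, 32)), 0.1)
        with pytest.raises(ValueError, match="bin"):
            alff(series, ONE_VOXEL_MASK)


class TestFalff:
    def test_in_band_tone_is_unit_fraction(self):
        n, tr = 290, 3.0
        f = on_bin_freq(0.05, n, tr)
        m = falff(single_voxel_series(tone(f, n, tr)), ONE_VOXEL_MASK)
        assert m.values[0, 0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_out_of_band_tone_is_zero_fraction(self):
        n, tr = 290, 3.0
        f = on_bin_freq(0.15, n, tr)
        m = falff(single_voxel_series(tone(f, n, tr)), ONE_VOXEL_MASK)
        assert m.values[0, 0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_white_noise_expectation_is_band_fraction(self, rng):
        n, tr = 1001, 3.0  # odd length avoids the special Nyquist bin
        freqs = np.fft.rfftfreq(n, tr)
        band_frac = ((freqs >= 0.01) & (freqs <= 0.1)).sum() / (freqs.size - 1)
        vals = []
        for _ in range(100):
            m = falff(single_voxel_series(rng.normal(size=n)), ONE_VOXEL_MASK)
            vals.append(m.values[0, 0, 0])
        assert np.mean(vals) == pytest.approx(band_frac, abs=0.02)

    def test_ratio_consistency_with_alff(self, rng):
        data = rng.normal(size=(3, 3, 2, 64))
        mask = np.ones((3, 3, 2), dtype=bool)
        series = BoldSeries(data, 3.0)
        a = alff(series, mask).values
        frac = falff(series, mask).values
        total = alff(series, mask, low_hz=0.0001, high_hz=1 / 6.0).values
        np.testing.assert_allclose(frac, a / total, rtol=1e-9)
        assert np.all(frac <= 1.0 + 1e-12)


class TestReho:
    def test_identical_series_perfectly_concordant(self):
        data = np.tile(np.sin(np.arange(30)), (3, 3, 3, 1))
        m = reho(BoldSeries(data, 3.0), np.ones((3, 3, 3), dtype=bool))
        assert m.values[1, 1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_series_near_null_expectation(self, rng):
        vals = []
        for _ in range(15):
            data = rng.normal(size=(3, 3, 3, 290))
            m = reho(BoldSeries(data, 3.0), np.ones((3, 3, 3), dtype=bool))
            vals.append(m.values[1, 1, 1])  # the only K=27 voxel
        assert max(vals) <= 0.08
        assert np.mean(vals) == pytest.approx(1 / 27, abs=0.01)

    def test_hand_computed_three_series(self):
        # rank table: [1,2,3,4], [2,1,4,3], [1,3,2,4] -> S = 29, W = 348/540
        data = np.zeros((3, 1, 1, 4))
        data[0, 0, 0] = [10, 20, 30, 40]
        data[1, 0, 0] = [15, 5, 40, 30]
        data[2, 0, 0] = [1, 5, 3, 9]
        mask = np.ones((3, 1, 1), dtype=bool)
        m = reho(BoldSeries(data, 3.0), mask)
        assert m.values[1, 0, 0] == pytest.approx(348 / 540, abs=1e-12)

    def test_matches_brute_force_everywhere(self, rng):
        shape = (6, 5, 4)
        data = rng.normal(size=shape + (40,))
        mask = rng.random(shape) > 0.2
        mask[2, 2, 2] = True
        m = reho(BoldSeries(data, 3.0), mask)
        expected = brute_reho(data, mask)
        np.testing.assert_allclose(m.values, expected, atol=1e-10)

    def test_isolated_voxel_flagged(self, rng):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        mask[4, 4, 4] = True
        m = reho(BoldSeries(rng.normal(size=(5, 5, 5, 20)), 3.0), mask)
        assert np.isnan(m.values[0, 0, 0])


class TestDegreeCentrality:
    def test_identical_series_fully_connected(self):
        data = np.tile(np.sin(np.arange(30.0)), (4, 3, 2, 1))
        mask = np.ones((4, 3, 2), dtype=bool)
        m = dc(BoldSeries(data, 3.0), mask)
        np.testing.assert_array_equal(m.values, 23.0)

    def test_orthogonal_tones_unconnected(self):
        n, tr = 60, 3.0
        data = np.zeros((2, 2, 1, n))
        for i, k in enumerate([3, 7, 11, 15]):
            data[np.unravel_index(i, (2, 2, 1))] = tone(k / (n * tr), n, tr)
        m = dc(BoldSeries(data, tr), np.ones((2, 2, 1), dtype=bool))
        np.testing.assert_array_equal(m.values, 0.0)

    def test_matches_brute_force_count(self, rng):
        shape = (10, 5, 4)  # 200 voxels
        data = rng.normal(size=shape + (60,))
        mask = np.ones(shape, dtype=bool)
        m = dc(BoldSeries(data, 3.0), mask)
        expected = brute_dc(data, mask)
        np.testing.assert_array_equal(m.values, expected)

    def test_invariant_to_affine_rescaling(self, rng):
        shape = (4, 4, 2)
        data = rng.normal(size=shape + (50,))
        mask = np.ones(shape, dtype=bool)
        scales = rng.uniform(0.5, 3.0, size=shape)[..., None]
        shifts = rng.normal(size=shape)[..., None]
        base = dc(BoldSeries(data, 3.0), mask)
        scaled = dc(BoldSeries(scales * data + shifts, 3.0), mask)
        np.testing.assert_array_equal(base.values, scaled.values)

    def test_zero_variance_voxel_flagged(self, rng):
        data = rng.normal(size=(3, 1, 1, 30))
        data[1, 0, 0] = 4.2
        m = dc(BoldSeries(data, 3.0), np.ones((3, 1, 1), dtype=bool))
        assert np.isnan(m.values[1, 0, 0])


class TestZscore:
    def test_standardizes_to_unit_moments(self, rng):
        mask = np.ones((6, 6, 4), dtype=bool)
        m = MetricMap(rng.normal(3, 2, size=(6, 6, 4)), "ALFF")
        z = zscore_map(m, mask)
        assert z.values[mask].mean() == pytest.approx(0.0, abs=1e-10)
        assert z.values[mask].std() == pytest.approx(1.0, abs=1e-10)
        assert z.standardized

    def test_idempotent_and_affine_invariant(self, rng):
        mask = np.ones((5, 5, 2), dtype=bool)
        vals = rng.normal(size=(5, 5, 2))
        z1 = zscore_map(MetricMap(vals, "ReHo"), mask)
        z2 = zscore_map(z1, mask)
        z3 = zscore_map(MetricMap(3.5 * vals + 1.2, "ReHo"), mask)
        np.testing.assert_allclose(z2.values, z1.values, atol=1e-10)
        np.testing.assert_allclose(z3.values, z1.values, atol=1e-10)

    def test_sentinels_untouched(self, rng):
        mask = np.ones((4, 4, 1), dtype=bool)
        vals = rng.normal(size=(4, 4, 1))
        vals[0, 0, 0] = np.nan
        z = zscore_map(MetricMap(vals, "DC"), mask)
        assert np.isnan(z.values[0, 0, 0])

    def test_constant_map_rejected(self):
        mask = np.ones((3, 3, 1), dtype=bool)
        with pytest.raises(ValueError):
            zscore_map(MetricMap(np.full((3, 3, 1), 2.0), "ALFF"), mask)


class TestSmoothing:
    def test_constant_field_unchanged(self):
        mask = np.ones((8, 8, 6), dtype=bool)
        m = MetricMap(np.full((8, 8, 6), 3.3), "ALFF")
        out = smooth_map(m, SmoothingSpec(3.0, (1.5, 1.5, 1.5)), mask)
        np.testing.assert_allclose(out.values, 3.3, atol=1e-10)
        assert out.smoothed_fwhm_mm == 3.0

    def test_impulse_response_matches_gaussian_kernel(self):
        shape = (25, 25, 25)
        mask = np.ones(shape, dtype=bool)
        vals = np.zeros(shape)
        vals[12, 12, 12] = 1.0
        spec = SmoothingSpec(3.0, (1.5, 1.5, 1.5))
        out = smooth_map(MetricMap(vals, "ALFF"), spec, mask)

        sigma_vox = spec.sigma_voxels()[0]
        radius = int(6.0 * sigma_vox + 0.5)
        offsets = np.arange(-radius, radius + 1)
        kernel = np.exp(-(offsets**2) / (2 * sigma_vox**2))
        kernel /= kernel.sum()
        center = kernel[radius]
        for d in range(radius + 1):
            expected = kernel[radius + d] * center * center
            assert out.values[12 + d, 12, 12] == pytest.approx(expected, abs=1e-6)

    def test_interior_mass_conserved(self, rng):
        shape = (20, 20, 16)
        mask = np.ones(shape, dtype=bool)
        vals = np.zeros(shape)
        vals[7:13, 7:13, 6:10] = rng.uniform(1, 2, size=(6, 6, 4))
        out = smooth_map(MetricMap(vals, "ALFF"), SmoothingSpec(3.0, (1.5, 1.5, 1.5)), mask)
        assert out.values[mask].sum() == pytest.approx(vals.sum(), rel=0.01)

    def test_narrow_kernel_approaches_identity(self, rng):
        shape = (8, 8, 4)
        mask = np.ones(shape, dtype=bool)
        vals = rng.normal(size=shape)
        out = smooth_map(MetricMap(vals, "DC"), SmoothingSpec(0.75, (1.5, 1.5, 1.5)), mask)
        np.testing.assert_allclose(out.values, vals, atol=1e-3)
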
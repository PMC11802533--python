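"""k-space truncation pipeline: transforms, truncation rule, pair synthesis."""

import numpy as np
import pytest

from perfdiff.degrade import (KSpaceFrame, augment_pair, degrade_image,
                              degrade_series, from_kspace, lowpass_image,
                              make_lr_hr_pair, retained_line_count, to_kspace,
                              truncate_phase_lines)
from perfdiff.evaluation import nrmse, ssim
from perfdiff.phantom import generate_series

from conftest import fast_config


def brute_force_dft2(img):
    """O(N^4) DFT with explicit sums, DC-centered — the independent oracle."""
    n, m = img.shape
    out = np.zeros((n, m), complex)
    for u in range(n):
        for v in range(m):
            s = 0.0
            for i in range(n):
                for j in range(m):
                    s += img[i, j] * np.exp(-2j * np.pi * (u * i / n + v * j / m))
            out[u, v] = s
    return np.roll(np.roll(out, n // 2, axis=0), m // 2, axis=1)


class TestToKSpace:
    def test_constant_image_all_energy_at_dc(self):
        n, c = 16, 0.7
        k = to_kspace(np.full((n, n), c))
        dc = n // 2
        assert k.grid[dc, dc] == pytest.approx(n * n * c)
        off = k.grid.copy()
        off[dc, dc] = 0
        assert np.abs(off).max() < 1e-9

    def test_roundtrip_identity(self, rng):
        img = rng.random((24, 24))
        back = from_kspace(to_kspace(img))
        assert np.abs(back - img).max() < 1e-10 * img.max()

    def test_matches_brute_force_dft_on_8x8(self, rng):
        img = rng.random((8, 8))
        np.testing.assert_allclose(to_kspace(img).grid, brute_force_dft2(img),
                                   atol=1e-9)

    def test_pure_cosine_two_lines_on_phase_axis(self):
        n, freq = 16, 3
        rows = np.arange(n)
        img = np.cos(2 * np.pi * freq * rows / n)[:, None] * np.ones((1, n))
        k = to_kspace(img)
        nz_rows = np.where(np.abs(k.grid).max(axis=1) > 1e-9)[0]
        np.testing.assert_array_equal(sorted(nz_rows), [n // 2 - freq, n // 2 + freq])

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            to_kspace(np.zeros((4, 4, 4)))


class TestTruncation:
    def test_fraction_one_is_identity(self, rng):
        k = to_kspace(rng.random((20, 20)))
        out = truncate_phase_lines(k, 1.0)
        np.testing.assert_array_equal(out.grid, k.grid)

    def test_retained_count_160_lines_at_35_percent(self):
        assert retained_line_count(0.35, 160) == 56
        grid = np.ones((160, 32), complex)
        out = truncate_phase_lines(KSpaceFrame(grid=grid), 0.35)
        nz = np.abs(out.grid).max(axis=1) > 0
        assert nz.sum() == 56

    @pytest.mark.parametrize("fraction,n_pe,expected", [
        (0.5, 10, 5), (0.33, 10, 3), (0.25, 10, 3),   # round half away from zero
        (0.30, 160, 48), (0.50, 160, 80), (1.0, 7, 7),
    ])
    def test_rounding_convention(self, fraction, n_pe, expected):
        assert retained_line_count(fraction, n_pe) == expected

    def test_band_contiguous_centered_dc_always_kept(self):
        for n_pe in (16, 17):
            for frac in (0.1, 0.3, 0.33, 0.5, 0.77):
                grid = np.ones((n_pe, 8), complex)
                out = truncate_phase_lines(KSpaceFrame(grid=grid), frac)
                nz = np.where(np.abs(out.grid).max(axis=1) > 0)[0]
                assert np.all(np.diff(nz) == 1)            # contiguous
                assert n_pe // 2 in nz                      # DC retained
                n_keep = retained_line_count(frac, n_pe)
                assert len(nz) == n_keep
                below = (nz < n_pe // 2).sum()
                above = (nz > n_pe // 2).sum()
                assert below - above == (0 if n_keep % 2 else 1)

    def test_phase_axis_configurable(self, rng):
        k = to_kspace(rng.random((12, 12)), phase_encode_axis=1)
        out = truncate_phase_lines(k, 0.25)
        nz_cols = np.abs(out.grid).max(axis=0) > 0
        assert nz_cols.sum() == retained_line_count(0.25, 12)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_fraction_out_of_range(self, bad):
        k = KSpaceFrame(grid=np.ones((8, 8), complex))
        with pytest.raises(ValueError):
            truncate_phase_lines(k, bad)

    def test_idempotent_at_same_fraction(self, rng):
        k = to_kspace(rng.random((32, 32)))
        once = truncate_phase_lines(k, 0.4)
        twice = truncate_phase_lines(once, 0.4)
        np.testing.assert_array_equal(once.grid, twice.grid)

    def test_energy_non_increasing(self, rng):
        k = to_kspace(rng.random((32, 32)))
        e0 = (np.abs(k.grid) ** 2).sum()
        for frac in (0.3, 0.5, 0.9):
            e = (np.abs(truncate_phase_lines(k, frac).grid) ** 2).sum()
            assert e < e0
        assert (np.abs(truncate_phase_lines(k, 1.0).grid) ** 2).sum() == pytest.approx(e0)

    def test_linear_before_magnitude(self, rng):
        i1, i2 = rng.random((16, 16)), rng.random((16, 16))
        a, b = 2.0, -0.7
        lhs = lowpass_image(a * i1 + b * i2, 0.4)
        rhs = a * lowpass_image(i1, 0.4) + b * lowpass_image(i2, 0.4)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def dirichlet_kernel(n, n_keep, lo):
    """Closed-form inverse DFT of an index-window indicator (periodic sinc)."""
    x = np.arange(n)
    ks = np.arange(lo, lo + n_keep) - n // 2     # signed retained frequencies
    return np.exp(2j * np.pi * np.outer(x, ks) / n).sum(axis=1) / n


class TestFromKSpace:
    def test_zero_grid_zero_image(self):
        assert np.all(from_kspace(KSpaceFrame(grid=np.zeros((8, 8), complex))) == 0)

    def test_magnitude_is_nonnegative_real(self, rng):
        img = from_kspace(to_kspace(rng.random((12, 12))))
        assert img.dtype.kind == "f" and np.all(img >= 0)

    def test_truncated_impulse_is_dirichlet_kernel(self):
        n = 32
        impulse = np.zeros((n, n))
        impulse[0, 0] = 1.0
        frac = 0.35
        lr = degrade_image(impulse, frac)
        n_keep = retained_line_count(frac, n)
        lo = n // 2 - n_keep // 2   # even n_keep: extra line below DC
        expected_rows = np.abs(dirichlet_kernel(n, n_keep, lo))
        np.testing.assert_allclose(lr[:, 0], expected_rows, atol=1e-8)
        # readout axis untouched: response along columns stays an impulse
        assert np.abs(lr[:, 1:]).max() < 1e-12


class TestMakePair:
    def test_fraction_one_pair_identical(self, small_series):
        pair = make_lr_hr_pair(small_series.frames[5], 1.0, crop_size=32)
        assert np.abs(pair.x - pair.y0).max() < 1e-9

    def test_ringing_confined_to_phase_axis(self):
        """Sharp-edge degradation equals row-wise convolution with the
        Dirichlet kernel; columns (readout) are not mixed."""
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        frac = 0.35
        lr_complex = lowpass_image(img, frac)
        n = 32
        n_keep = retained_line_count(frac, n)
        kern = dirichlet_kernel(n, n_keep, n // 2 - n_keep // 2)
        expected = np.empty_like(lr_complex)
        for col in range(n):
            f = np.asarray(img[:, col], complex)
            expected[:, col] = np.array(
                [np.sum(f * np.roll(kern[::-1], x + 1)) for x in range(n)])
        np.testing.assert_allclose(lr_complex, expected, atol=1e-9)

    def test_degradation_is_lossy_on_phantom(self, small_series):
        pair = make_lr_hr_pair(small_series.frames[8], 0.35, crop_size=32)
        assert nrmse(pair.x, pair.y0) > 0
        assert ssim(pair.x, pair.y0) < 1

    def test_shared_normalization_and_range(self, small_series):
        smax = float(small_series.frames.max())
        pair = make_lr_hr_pair(small_series.frames[8], 0.4, crop_size=32,
                               series_max=smax)
        assert pair.normalization.kind == "affine-to-[-1,1]"
        assert pair.y0.max() <= 1.0 + 1e-12 and pair.y0.min() >= -1.0 - 1e-12

    def test_crop_out_of_bounds(self, small_series):
        with pytest.raises(ValueError, match="out of bounds"):
            make_lr_hr_pair(small_series.frames[0], 0.4, crop_center=(2, 2),
                            crop_size=32)

    def test_roundtrip_identity_fraction_one_many_images(self, rng):
        for _ in range(100):
            img = rng.random((16, 16))
            pair = make_lr_hr_pair(img, 1.0, crop_size=16)
            assert np.abs(pair.x - pair.y0).max() < 1e-9


class TestAugment:
    def _pair(self, small_series):
        return make_lr_hr_pair(small_series.frames[6], 0.4, crop_size=32)

    def test_double_application_with_same_draws_restores(self, small_series):
        pair = self._pair(small_series)
        once = augment_pair(pair, np.random.default_rng(77))
        twice = augment_pair(once, np.random.default_rng(77))
        np.testing.assert_array_equal(twice.x, pair.x)
        np.testing.assert_array_equal(twice.y0, pair.y0)

    def test_flip_frequencies_near_half(self, small_series):
        """Each flip fires with empirical frequency within 3 sigma of 0.5."""
        pair = self._pair(small_series)
        rng = np.random.default_rng(123)
        n = 10_000
        v = h = 0
        for _ in range(n):
            out = augment_pair(pair, rng)
            # classify by comparing against the four possible outcomes
            flipped_v = np.array_equal(out.y0, pair.y0[::-1, :]) or \
                np.array_equal(out.y0, pair.y0[::-1, ::-1])
            flipped_h = np.array_equal(out.y0, pair.y0[:, ::-1]) or \
                np.array_equal(out.y0, pair.y0[::-1, ::-1])
            v += flipped_v
            h += flipped_h
        sigma = np.sqrt(0.25 / n)
        assert abs(v / n - 0.5) < 3 * sigma
        assert abs(h / n - 0.5) < 3 * sigma

    def test_x_and_y_flip_jointly(self, small_series):
        pair = self._pair(small_series)
        pair.x[3, 4] = 5.0   # marker pixel
        pair.y0[3, 4] = 7.0
        out = augment_pair(pair, np.random.default_rng(5))
        pos = np.argwhere(out.x == 5.0)[0]
        assert out.y0[tuple(pos)] == 7.0


class TestDegradeSeries:
    def test_masks_cropped_and_norm_shared(self, small_series):
        lr, hr = degrade_series(small_series, 0.35)
        assert lr.frames.shape == hr.frames.shape
        assert lr.normalization == hr.normalization
        assert set(lr.roi_masks) == set(small_series.roi_masks)
        np.testing.assert_array_equal(lr.frame_times, small_series.frame_times)
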
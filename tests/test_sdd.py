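import numpy as np
import pytest

from sddseg import (GradientHistogram, GrayImage, find_candidates, gradient_histogram,
                    gradient_image, intensity_histogram, sdd_profile_from_image,
                    select_range, slope_difference)
from sddseg.config import SDDConfig


def hist_from_profile(P):
    """Wrap a normalized profile as a histogram on integer levels."""
    P = np.asarray(P, dtype=float)
    return GradientHistogram(levels=np.arange(float(len(P))),
                             freq=np.rint(P * 1000).astype(np.int64),
                             P=P, f_max=1000.0)


def brute_force_candidates(profile):
    """Oracle: enumerate every +/- sign change of ds with positive s,
    independent of the library's crossing scan."""
    ds, s, levels = profile.ds, profile.s, profile.levels
    tol = 1e-9 * np.nanmax(np.abs(ds))
    tol_s = 1e-9 * np.nanmax(np.abs(s))
    found = []
    for i in range(len(ds) - 1):
        if np.isnan(ds[i]) or np.isnan(ds[i + 1]):
            continue
        if ds[i] > tol and ds[i + 1] <= tol:
            frac = ds[i] / (ds[i] - ds[i + 1]) if ds[i] != ds[i + 1] else 0.0
            if s[i] + frac * (s[i + 1] - s[i]) > tol_s:
                found.append(int(round(levels[i] + frac * (levels[i + 1] - levels[i]))))
    return sorted(set(found))


class TestGradientImage:
    def test_constant_image_has_zero_gradient(self):
        grad = gradient_image(GrayImage(np.full((16, 16), 9, dtype=np.int64)))
        assert np.all(grad.magnitude == 0)

    @pytest.mark.parametrize("h", [40, 100])
    def test_vertical_step_peak_on_step_columns_scales_with_height(self, h):
        px = np.zeros((16, 32), dtype=np.int64)
        px[:, 16:] = h
        grad = gradient_image(GrayImage(px))
        # Sobel/8 of a unit step peaks at h/2 on the two columns beside the edge
        assert grad.magnitude.max() == pytest.approx(h / 2)
        cols = np.unique(np.argwhere(grad.magnitude == grad.magnitude.max())[:, 1])
        assert set(cols) == {15, 16}

    def test_transpose_symmetry(self, rng):
        px = rng.integers(0, 256, (24, 40))
        g = gradient_image(GrayImage(px.astype(np.int64)))
        gt = gradient_image(GrayImage(px.T.astype(np.int64)))
        np.testing.assert_allclose(gt.magnitude, g.magnitude.T, atol=1e-12)
        np.testing.assert_allclose(gt.gx, g.gy.T, atol=1e-12)

    def test_invariant_under_added_constant(self, rng):
        px = rng.integers(0, 200, (16, 16))
        g0 = gradient_image(GrayImage(px.astype(np.int64)))
        g1 = gradient_image(GrayImage(px.astype(np.int64) + 50))
        np.testing.assert_allclose(g1.magnitude, g0.magnitude)

    def test_intensity_scaling_scales_magnitude(self, rng):
        px = rng.integers(0, 60, (16, 16)).astype(np.int64)
        g0 = gradient_image(GrayImage(px))
        g3 = gradient_image(GrayImage(px * 3))
        np.testing.assert_allclose(g3.magnitude, 3 * g0.magnitude, atol=1e-9)


class TestGradientHistogram:
    def test_two_values_equal_counts_both_normalize_to_one(self):
        px = np.zeros((16, 16), dtype=np.int64)
        px[:, 8:] = 100  # half the pixels dark, half bright
        hist = gradient_histogram(gradient_image(GrayImage(px)), n_bins=16)
        occupied = hist.P[hist.freq > 0]
        assert hist.P.max() == 1.0
        assert hist.freq.sum() == 256

    def test_counts_land_in_expected_bins(self):
        class FakeGrad:
            magnitude = np.concatenate([np.ones(100), np.full(50, 9.0)])
        # 16 uniform bins over [0, 9]: magnitude 1 falls in bin 1, 9 in the last
        hist = gradient_histogram(FakeGrad(), n_bins=16)
        assert hist.freq.sum() == 150
        bin_of_1 = int(np.digitize(1.0, np.linspace(0, 9, 17)) - 1)
        assert hist.freq[bin_of_1] == 100
        assert hist.freq[-1] == 50
        assert hist.P[bin_of_1] == 1.0
        assert hist.P[-1] == 0.5

    def test_constant_image_degenerate(self):
        grad = gradient_image(GrayImage(np.full((16, 16), 5, dtype=np.int64)))
        with pytest.raises(ValueError, match="degenerate"):
            gradient_histogram(grad)

    def test_intensity_histogram_bins_are_levels_for_8bit(self, rng):
        img = GrayImage(rng.integers(0, 256, (32, 32)).astype(np.int64))
        hist = intensity_histogram(img, 256)
        np.testing.assert_array_equal(hist.levels, np.arange(256))
        assert hist.freq.sum() == 32 * 32
        assert hist.P.max() == 1.0


class TestSlopeDifference:
    def test_linear_profile_has_zero_slope_difference(self):
        prof = slope_difference(hist_from_profile(np.linspace(0.05, 1, 64)),
                                fit_window=5, smooth_sigma=0)
        assert np.nanmax(np.abs(prof.s)) < 1e-12

    def test_triangle_apex_is_positive_peak(self):
        P = np.concatenate([np.linspace(0, 1, 33), np.linspace(1, 0, 33)[1:]])
        prof = slope_difference(hist_from_profile(P), 5, 0)
        assert np.nanargmax(prof.s) == 32
        assert prof.s[32] > 0

    def test_valley_is_negative(self):
        P = np.concatenate([np.linspace(1, 0.2, 31), np.linspace(0.2, 1, 31)[1:]])
        prof = slope_difference(hist_from_profile(P), 5, 0)
        assert prof.s[30] < 0

    def test_boundary_bins_undefined(self):
        prof = slope_difference(hist_from_profile(np.linspace(0, 1, 32)), 5, 0)
        assert np.all(np.isnan(prof.s[:5])) and np.all(np.isnan(prof.s[-5:]))

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            slope_difference(hist_from_profile(np.linspace(0, 1, 8)), 5, 0)


class TestFindCandidates:
    def test_single_triangle_peak(self):
        P = np.concatenate([np.linspace(0, 1, 41), np.linspace(1, 0, 41)[1:]])
        prof = find_candidates(slope_difference(hist_from_profile(P), 5, 0))
        assert prof.candidates == [40]

    def test_two_separated_peaks(self):
        x = np.arange(101.)
        P = np.exp(-0.5 * ((x - 25) / 6) ** 2) + 0.8 * np.exp(-0.5 * ((x - 75) / 6) ** 2)
        prof = find_candidates(slope_difference(hist_from_profile(P / P.max()), 5, 0))
        assert prof.candidates == [25, 75]

    def test_everywhere_nonpositive_raises(self):
        P = (np.arange(64.) / 63) ** 2  # convex: s < 0 at every interior bin
        with pytest.raises(ValueError, match="no cluster centers"):
            find_candidates(slope_difference(hist_from_profile(P), 5, 0))

    def test_agrees_with_brute_force_enumeration(self, rng):
        from scipy.ndimage import gaussian_filter1d
        for _ in range(20):
            P = gaussian_filter1d(rng.random(128), 3)
            P /= P.max()
            prof = slope_difference(hist_from_profile(P), 5, 0)
            try:
                got = find_candidates(prof).candidates
            except ValueError:
                got = []
            assert got == brute_force_candidates(prof)

    def test_two_gaussian_mixture_centers_recovered_within_two_bins(self, rng):
        # histogram of a well-separated two-Gaussian mixture sample
        samples = np.concatenate([rng.normal(60, 8, 40000), rng.normal(180, 10, 40000)])
        img = GrayImage(np.clip(np.rint(samples[:64 * 1250].reshape(800, 100)),
                                0, 255).astype(np.int64))
        prof = sdd_profile_from_image(img, SDDConfig(smooth_sigma=2.0))
        assert any(abs(c - 60) <= 2 for c in prof.candidates)
        assert any(abs(c - 180) <= 2 for c in prof.candidates)


class TestSelectRange:
    def make(self, cands):
        prof = slope_difference(hist_from_profile(
            np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]])), 5, 0)
        prof.candidates = list(cands)
        return prof

    def test_manual_interval_filter(self):
        prof = select_range(self.make([10, 40, 90]), "manual", 20, 95)
        assert prof.candidates == [40, 90]
        assert (prof.range_A, prof.range_B) == (20, 95)

    def test_auto_spans_candidates(self):
        prof = select_range(self.make([10, 40, 90]), "auto")
        assert prof.candidates == [10, 40, 90]
        assert (prof.range_A, prof.range_B) == (10, 90)

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError, match="no candidates inside"):
            select_range(self.make([10]), "manual", 20, 30)

    def test_inverted_limits_raise(self):
        with pytest.raises(ValueError, match="exceeds"):
            select_range(self.make([10, 40]), "manual", 50, 20)


def test_gradient_domain_maps_candidates_to_intensity_levels(rng):
    px = np.full((64, 64), 200, dtype=np.int64)
    px[16:48, 16:48] = 60
    px += rng.integers(-3, 4, px.shape)
    img = GrayImage(np.clip(px, 0, 255).astype(np.int64))
    prof = sdd_profile_from_image(img, SDDConfig(domain="gradient", smooth_sigma=2.0))
    assert all(0 <= c <= 255 for c in prof.candidates)
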
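import numpy as np
import pytest
from skimage import draw

from sddseg import (GrayImage, binarize, contour_perimeter, extract_contours,
                    label_components, postprocess, trace_boundary)


def disk_mask(r, pad=4):
    size = 2 * (r + pad) + 1
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw.disk((r + pad, r + pad), r + 0.5, shape=mask.shape)
    mask[rr, cc] = True
    return mask


class TestBinarize:
    def test_marks_dark_pixels(self, two_band_image):
        mask = binarize(two_band_image, 100, "dark")
        np.testing.assert_array_equal(mask, two_band_image.pixels == 60)

    def test_all_above_threshold_gives_empty_mask(self, two_band_image):
        assert not binarize(two_band_image, 10, "dark").any()

    def test_inversion_identity(self, rng):
        img = GrayImage(rng.integers(0, 256, (24, 24)).astype(np.int64))
        t = 130
        np.testing.assert_array_equal(
            binarize(img, t, "dark"),
            binarize(img.invert(), 255 - t, "bright"))


class TestPostprocess:
    def test_small_component_removed(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[4, 4:7] = True  # 3-pixel component
        assert not postprocess(mask, min_area=5).any()

    def test_solid_disk_survives_convexity_filter(self):
        mask = disk_mask(10)
        out = postprocess(mask, min_area=0, fill_holes=False, convexity_min=0.8)
        np.testing.assert_array_equal(out, mask)

    def test_thin_curve_removed_by_convexity_filter(self):
        mask = np.zeros((64, 64), dtype=bool)
        t = np.linspace(0, 2.5 * np.pi, 400)
        rr = np.clip((32 + 20 * np.sin(t)).astype(int), 0, 63)
        cc = np.clip((8 + 48 * t / t.max()).astype(int), 0, 63)
        mask[rr, cc] = True  # 1 px wide S-shaped curve
        out = postprocess(mask, min_area=0, fill_holes=False, convexity_min=0.8)
        assert not out.any()

    def test_max_area_filter(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[2:6, 2:6] = True      # 16 px
        mask[10:26, 10:26] = True  # 256 px
        out = postprocess(mask, min_area=0, fill_holes=False, max_area=100)
        assert out.sum() == 16

    def test_hole_filling_optional(self):
        mask = disk_mask(8)
        mask[12, 12] = False
        assert postprocess(mask, fill_holes=True)[12, 12]
        assert not postprocess(mask, fill_holes=False)[12, 12]

    def test_idempotent(self, rng):
        for _ in range(5):
            mask = rng.random((48, 48)) < 0.35
            once = postprocess(mask, min_area=9, fill_holes=True, convexity_min=0.6)
            twice = postprocess(once, min_area=9, fill_holes=True, convexity_min=0.6)
            np.testing.assert_array_equal(once, twice)

    def test_component_count_monotone_in_min_area(self, rng):
        mask = rng.random((64, 64)) < 0.3
        counts = [label_components(postprocess(mask, min_area=a, fill_holes=False)
                                   ).n_components for a in (0, 2, 5, 10, 20)]
        assert counts == sorted(counts, reverse=True)

    def test_negative_min_area_rejected(self):
        with pytest.raises(ValueError):
            postprocess(np.zeros((8, 8), dtype=bool), min_area=-1)


class TestLabelComponents:
    def test_two_disjoint_squares(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        res = label_components(mask)
        assert res.n_components == 2
        assert sorted(res.areas.values()) == [9, 9]

    def test_empty_mask(self):
        res = label_components(np.zeros((16, 16), dtype=bool))
        assert res.n_components == 0 and res.areas == {}

    def test_diagonal_touch_is_one_component_under_8_connectivity(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2:5, 2:5] = True
        mask[5:8, 5:8] = True  # corner contact at (5,5)/(4,4)
        assert label_components(mask).n_components == 1

    def test_labels_positive_exactly_on_mask(self, rng):
        mask = rng.random((32, 32)) < 0.3
        res = label_components(mask)
        np.testing.assert_array_equal(res.labels > 0, mask)
        assert res.n_components == len(np.unique(res.labels)) - 1


class TestContours:
    def test_square_boundary_has_36_pixels(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True  # 10x10 square: boundary ring = 4*10 - 4
        res = label_components(mask)
        contours = extract_contours(res, "boundary")
        assert len(contours[1]) == 36

    def test_single_pixel_component(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 3] = True
        chain = extract_contours(label_components(mask), "boundary")[1]
        np.testing.assert_array_equal(chain, [[3, 3]])

    @pytest.mark.parametrize("r", [10, 15, 20])
    def test_disk_perimeter_close_to_circumference(self, r):
        chain = trace_boundary(disk_mask(r))
        assert contour_perimeter(chain) == pytest.approx(2 * np.pi * r, rel=0.15)

    def test_chain_closed_and_8_connected(self):
        chain = trace_boundary(disk_mask(7))
        steps = np.abs(np.diff(np.vstack([chain, chain[:1]]), axis=0))
        assert steps.max() <= 1  # every step is to an 8-neighbor

    def test_every_contour_pixel_touches_background(self, rng):
        mask = postprocess(rng.random((48, 48)) < 0.4, min_area=5, fill_holes=True)
        res = label_components(mask)
        contours = extract_contours(res, "boundary")
        padded = np.pad(mask, 1)
        for chain in contours.values():
            for row, col in chain:
                neigh = padded[row:row + 3, col:col + 3]
                assert not neigh.all(), "contour pixel not on the boundary"

    def test_canny_contours_assign_edges_to_components(self, two_band_image):
        res = label_components(binarize(two_band_image, 100))
        contours = extract_contours(res, "canny", intensity=two_band_image)
        assert set(contours) == {1}
        assert len(contours[1]) > 0

    def test_unknown_method_rejected(self, two_band_image):
        res = label_components(binarize(two_band_image, 100))
        with pytest.raises(ValueError):
            extract_contours(res, "snake")
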
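"""Unit and property tests of the morphology primitives against
brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neurimetrics.morphology import (
    GreyImage,
    StructuringElement,
    binarize,
    dilate,
    erode,
    find_endpoints,
    grey_open,
    size_filter,
    skeletonize,
    subtract,
)

from _oracles import (
    brute_dilate_binary,
    brute_open_grey,
    count_holes,
    graph_leaf_endpoints,
    label_filter_oracle,
)

DISK3 = StructuringElement("disk", 3)


def _img(arr, bits=8):
    return GreyImage(np.asarray(arr), bit_depth=bits)


@st.composite
def grey_images(draw, shape=(18, 18)):
    data = draw(st.lists(st.integers(0, 255), min_size=shape[0] * shape[1],
                         max_size=shape[0] * shape[1]))
    return _img(np.array(data, dtype=np.uint8).reshape(shape))


class TestGreyOpen:
    def test_uniform_image_is_fixed_point(self):
        img = _img(np.full((32, 32), 100, dtype=np.uint8))
        assert np.array_equal(grey_open(img, DISK3).pixels, img.pixels)

    def test_thin_line_suppressed_to_background(self):
        arr = np.full((40, 40), 10, dtype=np.uint8)
        arr[20, 5:35] = 200
        opened = grey_open(_img(arr), DISK3)
        assert np.all(opened.pixels[20, 5:35] <= 10)

    def test_wide_disk_interior_preserved_matches_brute_force(self):
        arr = np.full((40, 40), 10, dtype=np.uint8)
        yy, xx = np.mgrid[:40, :40]
        arr[(yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2] = 180
        opened = grey_open(_img(arr), DISK3)
        expected = brute_open_grey(arr, DISK3.footprint())
        assert np.array_equal(opened.pixels.astype(float), expected)
        assert opened.pixels[20, 20] == 180

    def test_random_image_matches_brute_force(self, rng):
        arr = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        opened = grey_open(_img(arr), StructuringElement("square", 1))
        expected = brute_open_grey(arr, np.ones((3, 3), bool))
        assert np.array_equal(opened.pixels.astype(float), expected)

    def test_oversized_se_rejected(self):
        with pytest.raises(ValueError, match="exceeds image"):
            grey_open(_img(np.zeros((10, 10), dtype=np.uint8)),
                      StructuringElement("disk", 6))

    @given(grey_images())
    def test_anti_extensive_idempotent_monotone(self, img):
        opened = grey_open(img, StructuringElement("disk", 2))
        assert np.all(opened.pixels <= img.pixels)
        again = grey_open(opened, StructuringElement("disk", 2))
        assert np.array_equal(again.pixels, opened.pixels)
        brighter = GreyImage(np.minimum(img.pixels.astype(int) + 30, 255), bit_depth=8)
        opened_b = grey_open(brighter, StructuringElement("disk", 2))
        assert np.all(opened_b.pixels >= opened.pixels)


class TestSubtract:
    def test_identical_images_give_zero(self):
        a = _img(np.full((8, 8), 77, dtype=np.uint8))
        assert not subtract(a, a).pixels.any()

    def test_clamped_at_zero_never_wraps(self):
        a = _img(np.full((8, 8), 50, dtype=np.uint8))
        b = _img(np.full((8, 8), 80, dtype=np.uint8))
        assert not subtract(a, b).pixels.any()

    def test_isolates_line_over_opened_background(self, rng):
        arr = np.full((30, 30), 20, dtype=np.uint8)
        arr[15] = 200
        img = _img(arr)
        opened = grey_open(img, DISK3)
        diff = subtract(img, opened)
        expected = np.maximum(arr.astype(float) - opened.pixels.astype(float), 0)
        assert np.array_equal(diff.pixels, expected)
        assert np.all(diff.pixels[15, 3:-3] > 150)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            subtract(_img(np.zeros((4, 4), np.uint8)), _img(np.zeros((4, 5), np.uint8)))


class TestBinarize:
    def test_threshold_zero_on_zero_image_is_empty(self):
        assert not binarize(_img(np.zeros((6, 6), np.uint8)), 0).any()

    def test_strictly_above_threshold(self):
        arr = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        assert np.array_equal(binarize(_img(arr), 0), arr.astype(bool))

    def test_matches_per_pixel_comparison(self, rng):
        arr = rng.integers(0, 256, (50, 50)).astype(np.uint8)
        assert np.array_equal(binarize(_img(arr), 128), arr > 128)

    @given(grey_images(), st.sampled_from([0.5, 2.0, 3.0]),
           st.integers(10, 240))
    def test_scale_invariance(self, img, k, threshold):
        # the algorithmic basis for staining-intensity robustness
        scaled = GreyImage(img.pixels.astype(np.float64) * k, bit_depth=16)
        assert np.array_equal(binarize(scaled, threshold * k),
                              binarize(img, threshold))


class TestSizeFilter:
    def test_empty_mask_passes_through(self):
        assert not size_filter(np.zeros((10, 10), bool), 5).any()

    def test_removes_speck_enclosed_by_ring(self):
        mask = np.zeros((40, 40), bool)
        yy, xx = np.mgrid[:40, :40]
        r2 = (yy - 20) ** 2 + (xx - 20) ** 2
        ring = (r2 <= 15**2) & (r2 >= 12**2)
        mask |= ring
        mask[19:21, 19:21] = True  # 4-px speck trapped inside the loop
        out = size_filter(mask, 10)
        assert np.array_equal(out, ring)

    def test_matches_label_threshold_oracle(self, rng):
        from scipy import ndimage as ndi

        blobs = ndi.gaussian_filter(rng.normal(size=(80, 80)), 2.0) > 0.3
        assert np.array_equal(size_filter(blobs, 25),
                              label_filter_oracle(blobs, 25))

    def test_idempotent(self, rng):
        from scipy import ndimage as ndi

        blobs = ndi.gaussian_filter(rng.normal(size=(60, 60)), 2.0) > 0.25
        once = size_filter(blobs, 20)
        assert np.array_equal(size_filter(once, 20), once)


class TestSkeletonize:
    def test_bar_reduces_to_axis(self):
        mask = np.zeros((20, 60), bool)
        mask[9:12, 5:55] = True
        skel = skeletonize(mask)
        assert skel.sum() == pytest.approx(50, abs=2)
        assert np.all(mask[skel])
        # one pixel wide: no full 2x2 block anywhere
        two_by_two = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        assert not two_by_two.any()

    def test_single_pixel_is_preserved(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert np.array_equal(skeletonize(mask), mask)

    def test_filled_disk_homotopy(self):
        from scipy import ndimage as ndi

        yy, xx = np.mgrid[:30, :30]
        disk = (yy - 15) ** 2 + (xx - 15) ** 2 <= 8**2
        skel = skeletonize(disk)
        _, n = ndi.label(skel, structure=np.ones((3, 3)))
        assert n == 1
        assert count_holes(skel) == 0


class TestFindEndpoints:
    def test_straight_path_has_two_termini(self):
        skel = np.zeros((10, 60), bool)
        skel[5, 5:55] = True
        ep = find_endpoints(skel)
        assert ep.sum() == 2
        assert ep[5, 5] and ep[5, 54]

    def test_y_shape_has_three_tips(self):
        skel = np.zeros((30, 30), bool)
        skel[15, 5:16] = True              # stem
        for i in range(1, 10):             # two diagonal arms
            skel[15 - i, 15 + i] = True
            skel[15 + i, 15 + i] = True
        assert find_endpoints(skel).sum() == 3

    def test_closed_ring_has_no_endpoints(self):
        skel = np.zeros((20, 20), bool)
        skel[5, 5:15] = skel[14, 5:15] = True
        skel[5:15, 5] = skel[5:15, 14] = True
        assert find_endpoints(skel).sum() == 0

    def test_matches_graph_and_erode_subtract_oracles(self, rng):
        from conftest import random_skeleton
        from _oracles import erode_subtract_endpoints

        for _ in range(20):
            skel = random_skeleton(rng)
            ours = find_endpoints(skel)
            assert np.array_equal(ours, graph_leaf_endpoints(skel))
            assert np.array_equal(ours, erode_subtract_endpoints(skel))


class TestBinaryDilateErode:
    def test_empty_mask_stays_empty(self):
        assert not dilate(np.zeros((10, 10), bool), DISK3).any()

    def test_single_pixel_becomes_disk(self):
        mask = np.zeros((11, 11), bool)
        mask[5, 5] = True
        out = dilate(mask, StructuringElement("disk", 2))
        yy, xx = np.mgrid[:11, :11]
        assert np.array_equal(out, (yy - 5) ** 2 + (xx - 5) ** 2 <= 4)

    def test_matches_union_of_translates_oracle(self, rng):
        mask = rng.random((24, 24)) > 0.85
        out = dilate(mask, DISK3)
        assert np.array_equal(out, brute_dilate_binary(mask, DISK3.footprint()))
        assert np.all(out[mask])  # extensivity

    @given(st.integers(0, 2**20 - 1))
    def test_opening_closing_sandwich(self, bits):
        mask = np.array([(bits >> i) & 1 for i in range(20)], dtype=bool)
        mask = np.tile(mask, (20, 1))
        mask[0] = mask[-1] = mask[:, 0] = mask[:, -1] = False  # closing is
        # extensive only away from the image border (border = background)
        se = StructuringElement("disk", 1)
        opening = dilate(erode(mask, se), se)
        closing = erode(dilate(mask, se), se)
        assert np.all(~mask | closing)   # mask <= closing
        assert np.all(~opening | mask)   # opening <= mask


class TestStructuringElement:
    @pytest.mark.parametrize("shape,radius", [("disk", 0), ("hex", 2)])
    def test_invalid_parameters_rejected(self, shape, radius):
        with pytest.raises(ValueError):
            StructuringElement(shape, radius)

    def test_footprint_shapes(self):
        assert StructuringElement("square", 2).footprint().shape == (5, 5)
        disk = StructuringElement("disk", 2).footprint()
        assert disk.shape == (5, 5) and not disk[0, 0]
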
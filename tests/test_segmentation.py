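"""Unit and property tests for the segmentation pipeline stages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.base import clone

from dermoseg.segmentation import (
    LesionSegmenter,
    SegmentationConfig,
    decompose_bit_plane,
    extract_msb_planes,
    lesion_mask_from_levels,
    lowpass_quantize,
    make_hanning_kernel,
    segment,
    sum_planes,
    trace_border,
)

from conftest import boundary_oracle, brute_force_lowpass_quantize

rgb_images = arrays(
    np.uint8, st.tuples(st.integers(4, 16), st.integers(4, 16), st.just(3))
)


class TestBitPlanes:
    def test_msb_boundary_at_128(self):
        img = np.zeros((1, 2, 3), dtype=np.uint8)
        img[0, 0, 0] = 127
        img[0, 1, 0] = 128
        r, g, b = extract_msb_planes(img)
        assert r[0, 0] == 0 and r[0, 1] == 1
        assert not g.any() and not b.any()

    def test_value_128_only_sets_bit7(self):
        img = np.full((1, 1, 3), 128, dtype=np.uint8)
        assert decompose_bit_plane(img, "R", 7) == 1
        for bit in range(7):
            assert decompose_bit_plane(img, "R", bit) == 0

    def test_value_255_sets_every_bit(self):
        img = np.full((2, 2, 3), 255, dtype=np.uint8)
        for bit in range(8):
            assert decompose_bit_plane(img, "G", bit).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(rgb_images)
    def test_bit_planes_reconstruct_channels_exactly(self, img):
        for c in range(3):
            recon = sum(
                decompose_bit_plane(img, c, bit).astype(np.int64) << bit
                for bit in range(8)
            )
            np.testing.assert_array_equal(recon, img[:, :, c])

    def test_msb_equals_threshold_rule(self, random_rgb):
        for _ in range(20):
            img = random_rgb(64, 64)
            planes = extract_msb_planes(img)
            for c in range(3):
                np.testing.assert_array_equal(planes[c], img[:, :, c] >= 128)

    def test_bit_out_of_range_rejected(self, random_rgb):
        with pytest.raises(ValueError):
            decompose_bit_plane(random_rgb(4, 4), "R", 8)
        with pytest.raises(ValueError):
            decompose_bit_plane(random_rgb(4, 4), "X", 7)


class TestHanningKernel:
    def test_1d_window_closed_form(self):
        # w[n] = 0.5 * (1 - cos(2*pi*n/6)) for a 7-tap window
        expected = np.array([0.0, 0.25, 0.75, 1.0, 0.75, 0.25, 0.0])
        np.testing.assert_allclose(np.hanning(7), expected, atol=1e-12)

    def test_kernel_algebra(self):
        k = make_hanning_kernel(7)
        assert k.shape == (7, 7)
        assert abs(k.sum() - 1.0) < 1e-12
        assert (k >= 0).all()
        np.testing.assert_allclose(k, np.fliplr(k), atol=0)
        np.testing.assert_allclose(k, np.flipud(k), atol=0)
        np.testing.assert_allclose(k, k.T, atol=0)
        # zero-endpoint window: the outer frame of the kernel is exactly 0
        assert (k[0, :] == 0).all() and (k[:, 0] == 0).all()
        assert abs(k[3, 3] - 1.0 / 9.0) < 1e-12

    @pytest.mark.parametrize("size", [2, 4, 1, 0, -3])
    def test_bad_sizes_rejected(self, size):
        with pytest.raises(ValueError):
            make_hanning_kernel(size)


class TestLowpassQuantize:
    def test_all_ones_stay_ones(self):
        plane = np.ones((15, 12), dtype=np.uint8)
        np.testing.assert_array_equal(lowpass_quantize(plane), plane)

    def test_isolated_one_is_removed(self):
        plane = np.zeros((11, 11), dtype=np.uint8)
        plane[5, 5] = 1
        assert not lowpass_quantize(plane).any()

    def test_isolated_zero_is_restored(self):
        plane = np.ones((11, 11), dtype=np.uint8)
        plane[5, 5] = 0
        assert lowpass_quantize(plane).all()

    def test_isolated_pixel_anywhere_is_invariant(self, rng):
        # adding/removing one isolated pixel never changes the output
        for base_val in (0, 1):
            base = np.full((20, 20), base_val, dtype=np.uint8)
            ref = lowpass_quantize(base)
            for _ in range(10):
                i, j = rng.integers(0, 20, size=2)
                plane = base.copy()
                plane[i, j] = 1 - base_val
                np.testing.assert_array_equal(lowpass_quantize(plane), ref)

    def test_block_interior_is_preserved(self):
        plane = np.zeros((20, 20), dtype=np.uint8)
        plane[5:15, 5:15] = 1
        out = lowpass_quantize(plane)
        assert out[8:12, 8:12].all()  # Chebyshev distance >= 3 from block edge

    def test_matches_brute_force_convolution(self, random_plane):
        kernel = make_hanning_kernel()
        for _ in range(5):
            plane = random_plane(16, 16)
            expected = brute_force_lowpass_quantize(plane, kernel)
            np.testing.assert_array_equal(lowpass_quantize(plane, kernel), expected)

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.1, 1.5])
    def test_bad_threshold_rejected(self, threshold):
        with pytest.raises(ValueError):
            lowpass_quantize(np.zeros((5, 5), dtype=np.uint8), threshold=threshold)

    def test_non_binary_plane_rejected(self):
        with pytest.raises(ValueError):
            lowpass_quantize(np.full((5, 5), 2, dtype=np.uint8))


class TestSumPlanes:
    def test_single_plane_contributions(self):
        one = np.ones((3, 3), dtype=np.uint8)
        zero = np.zeros((3, 3), dtype=np.uint8)
        assert (sum_planes(one, one, one) == 3).all()
        assert (sum_planes(one, zero, zero) == 1).all()

    def test_matches_elementwise_sum_and_range(self, random_plane):
        for _ in range(10):
            planes = [random_plane(12, 9) for _ in range(3)]
            levels = sum_planes(*planes)
            expected = np.zeros((12, 9), dtype=int)
            for p in planes:
                expected += p
            np.testing.assert_array_equal(levels, expected)
            assert levels.min() >= 0 and levels.max() <= 3

    def test_shape_mismatch_rejected(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 5), dtype=np.uint8)
        with pytest.raises(ValueError):
            sum_planes(a, a, b)


class TestLesionMask:
    def test_all_skin_gives_empty_mask(self):
        levels = np.full((16, 16), 3, dtype=np.uint8)
        assert not lesion_mask_from_levels(levels).any()

    def test_central_dark_disk_is_recovered(self):
        levels = np.full((32, 32), 3, dtype=np.uint8)
        yy, xx = np.mgrid[0:32, 0:32]
        disk = (yy - 16) ** 2 + (xx - 16) ** 2 < 8**2
        levels[disk] = 0
        np.testing.assert_array_equal(lesion_mask_from_levels(levels), disk)

    def test_corner_wedges_excluded_central_blob_kept(self):
        levels = np.full((40, 40), 3, dtype=np.uint8)
        yy, xx = np.mgrid[0:40, 0:40]
        blob = (yy - 20) ** 2 + (xx - 20) ** 2 < 10**2
        levels[blob] = 1
        for cy, cx in ((0, 0), (0, 39), (39, 0), (39, 39)):
            wedge = (yy - cy) ** 2 + (xx - cx) ** 2 < 6**2
            levels[wedge] = 0
        mask = lesion_mask_from_levels(levels).astype(bool)
        np.testing.assert_array_equal(mask, blob)

    def test_largest_component_selection_against_flood_fill(self):
        from scipy import ndimage

        levels = np.full((30, 30), 3, dtype=np.uint8)
        levels[5:10, 5:10] = 0  # 25 px
        levels[18:28, 15:27] = 0  # 120 px
        mask = lesion_mask_from_levels(levels).astype(bool)
        lab, n = ndimage.label(levels <= 2, structure=np.ones((3, 3), bool))
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        np.testing.assert_array_equal(mask, lab == sizes.argmax())

    def test_hole_filling(self):
        levels = np.full((20, 20), 3, dtype=np.uint8)
        levels[5:15, 5:15] = 0
        levels[9:11, 9:11] = 3  # bright hole inside the lesion
        mask = lesion_mask_from_levels(levels)
        assert mask[9:11, 9:11].all()
        cfg = SegmentationConfig(fill_holes=False)
        assert not lesion_mask_from_levels(levels, cfg)[9:11, 9:11].any()

    def test_raising_level_max_never_shrinks_candidates(self, rng):
        levels = rng.integers(0, 4, size=(25, 25))
        cfg_off = dict(
            exclude_corner_components=False,
            keep_largest_component=False,
            fill_holes=False,
        )
        prev = np.zeros((25, 25), dtype=bool)
        for lmax in (0, 1, 2):
            cand = lesion_mask_from_levels(
                levels, SegmentationConfig(lesion_level_max=lmax, **cfg_off)
            ).astype(bool)
            assert (prev <= cand).all()
            prev = cand

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            lesion_mask_from_levels(np.full((4, 4), 5))


class TestTraceBorder:
    def test_empty_mask_gives_empty_contour(self):
        contour = trace_border(np.zeros((5, 5), dtype=np.uint8))
        assert contour.shape == (0, 2)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 3] = 1
        contour = trace_border(mask)
        np.testing.assert_array_equal(contour, [[2, 3]])

    def test_filled_3x3_square_has_8_boundary_pixels(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        contour = trace_border(mask)
        assert len(set(map(tuple, contour))) == 8
        assert (3, 3) not in set(map(tuple, contour))  # interior pixel excluded
        assert tuple(contour[0]) == (2, 2)

    def test_contour_properties_on_blobs(self, rng):
        from scipy import ndimage

        for _ in range(5):
            raw = rng.random((40, 40)) < 0.5
            blob = ndimage.binary_closing(
                ndimage.binary_opening(raw, np.ones((3, 3))), np.ones((5, 5))
            )
            blob = ndimage.binary_fill_holes(blob)
            lab, n = ndimage.label(blob, structure=np.ones((3, 3), bool))
            if n == 0:
                continue
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            mask = (lab == sizes.argmax()).astype(np.uint8)
            contour = trace_border(mask)
            # traced set == morphological 4-neighbour boundary
            assert set(map(tuple, contour)) == set(
                map(tuple, np.argwhere(boundary_oracle(mask)))
            )
            # consecutive points are 8-neighbours; the path is closed
            steps = np.abs(np.diff(contour, axis=0)).max(axis=1)
            assert (steps == 1).all()
            assert np.abs(contour[0] - contour[-1]).max() <= 1
            # starts at the topmost-then-leftmost boundary pixel
            rows, cols = np.nonzero(mask)
            assert tuple(contour[0]) == (rows[0], cols[0])

    def test_orientation_is_counterclockwise_on_screen(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        yy, xx = np.mgrid[0:30, 0:30]
        mask[(yy - 15) ** 2 + (xx - 15) ** 2 < 10**2] = 1
        c = trace_border(mask).astype(float)
        x, y = c[:, 1], -c[:, 0]  # screen coords, y up
        signed2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert signed2 > 0


class TestEndToEnd:
    def test_uniform_bright_image(self):
        img = np.full((24, 24, 3), 200, dtype=np.uint8)
        res = segment(img)
        assert (res.levels == 3).all()
        assert not res.mask.any()
        assert res.contour.shape == (0, 2)

    def test_uniform_dark_image(self):
        img = np.full((24, 24, 3), 50, dtype=np.uint8)
        res = segment(img)
        assert (res.levels == 0).all()
        # the whole frame touches the corners: excluded by default
        assert not res.mask.any()

    def test_segment_is_deterministic(self, random_rgb):
        img = random_rgb(48, 48)
        a = segment(img)
        b = segment(img)
        np.testing.assert_array_equal(a.levels, b.levels)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.contour, b.contour)

    def test_segment_matches_stage_composition(self, random_rgb):
        img = random_rgb(32, 32)
        cfg = SegmentationConfig()
        kernel = make_hanning_kernel(cfg.kernel_size)
        planes = [
            lowpass_quantize(p, kernel, cfg.quantize_threshold)
            for p in extract_msb_planes(img, cfg.bit_index)
        ]
        levels = sum_planes(*planes)
        mask = lesion_mask_from_levels(levels, cfg)
        res = segment(img, cfg)
        np.testing.assert_array_equal(res.levels, levels)
        np.testing.assert_array_equal(res.mask, mask)
        np.testing.assert_array_equal(res.contour, trace_border(mask))

    def test_level_map_range_invariant(self, random_rgb):
        res = segment(random_rgb(40, 40))
        assert res.levels.min() >= 0 and res.levels.max() <= 3


class TestConfigAndEstimator:
    def test_config_ini_round_trip(self, tmp_path):
        cfg = SegmentationConfig(lesion_level_max=1, quantize_threshold=0.4,
                                 fill_holes=False)
        path = tmp_path / "seg.ini"
        cfg.to_ini(path)
        assert SegmentationConfig.from_ini(path) == cfg

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SegmentationConfig(bit_index=9).validate()
        with pytest.raises(ValueError):
            SegmentationConfig(lesion_level_max=3).validate()
        with pytest.raises(ValueError):
            SegmentationConfig(quantize_threshold=1.0).validate()

    def test_estimator_sklearn_surface(self, random_rgb):
        est = LesionSegmenter(lesion_level_max=1)
        assert clone(est).get_params() == est.get_params()
        est.set_params(lesion_level_max=2).fit()
        assert est.config_.lesion_level_max == 2
        assert est.kernel_.shape == (7, 7)
        img = random_rgb(32, 32)
        np.testing.assert_array_equal(est.predict(img), segment(img).mask)
        masks = est.predict([img, img])
        assert len(masks) == 2
        np.testing.assert_array_equal(est.transform(img), segment(img).levels)
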
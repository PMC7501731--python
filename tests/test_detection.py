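"""Tests of the tiled detection stage: filtering, thresholding, tiling
invariance, merging, hole filling and particle-area filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from hepaquant import (DetectionParams, MultiplexImage, detect_macrophages,
                       median_filter_channel, threshold_channel)
from hepaquant.detection import detections_to_label_image, fill_holes

from oracles import brute_force_median, exhaustive_otsu, lattice_disk_count


def _image(f480, pixel_size=1.0):
    return MultiplexImage(channels={"F4/80": np.asarray(f480, dtype=float)},
                          pixel_size=pixel_size, image_id="t")


def _disk_image(shape, centers, radius, fg=200.0, bg=10.0):
    arr = np.full(shape, bg)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for r0, c0 in centers:
        arr[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2] = fg
    return arr


class TestMedianFilter:
    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(16, 16))
        np.testing.assert_array_equal(median_filter_channel(img, 0), img)

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_constant_image_unchanged(self, radius):
        img = np.full((20, 20), 7.0)
        np.testing.assert_array_equal(median_filter_channel(img, radius), img)

    def test_salt_pixel_removed(self):
        img = np.full((15, 15), 10.0)
        img[7, 7] = 255.0
        out = median_filter_channel(img, 2)
        np.testing.assert_array_equal(out, np.full((15, 15), 10.0))

    @pytest.mark.parametrize("radius", [1, 2])
    def test_matches_exhaustive_window_median(self, radius):
        rng = np.random.default_rng(42)
        img = rng.integers(0, 50, size=(18, 14)).astype(float)
        np.testing.assert_array_equal(median_filter_channel(img, radius),
                                      brute_force_median(img, radius))

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            median_filter_channel(np.zeros((4, 4)), -1)


class TestThreshold:
    def test_fixed_threshold_ge_convention(self):
        img = np.array([[99.0, 100.0, 101.0]])
        params = DetectionParams(threshold_mode="fixed", threshold_value=100)
        np.testing.assert_array_equal(
            threshold_channel(img, params), [[False, True, True]])

    def test_global_otsu_on_bimodal_equals_exhaustive_search(self):
        rng = np.random.default_rng(1)
        img = np.where(rng.random((40, 40)) < 0.3, 200.0, 10.0)
        params = DetectionParams(threshold_mode="global-otsu")
        mask = threshold_channel(img, params)
        np.testing.assert_array_equal(mask, img >= exhaustive_otsu(img))
        np.testing.assert_array_equal(mask, img == 200.0)

    def test_all_zero_fixed_threshold_one_is_empty(self):
        params = DetectionParams(threshold_mode="fixed", threshold_value=1)
        assert not threshold_channel(np.zeros((8, 8)), params).any()

    def test_constant_image_otsu_falls_back_to_background(self, caplog):
        params = DetectionParams(threshold_mode="global-otsu")
        with caplog.at_level("WARNING"):
            mask = threshold_channel(np.full((8, 8), 5.0), params)
        assert not mask.any()
        assert "constant" in caplog.text


class TestDetect:
    def test_all_background_gives_empty_list(self):
        image = _image(np.full((128, 128), 10.0))
        params = DetectionParams(threshold_mode="fixed", threshold_value=100)
        assert detect_macrophages(image, params) == []

    def test_missing_f480_channel_errors(self):
        image = MultiplexImage(channels={"TIM4": np.zeros((8, 8))},
                               pixel_size=1.0)
        with pytest.raises(KeyError, match="F4/80"):
            detect_macrophages(image, DetectionParams())

    def test_disk_areas_match_lattice_enumeration(self):
        centers = [(30, 30), (30, 90), (90, 30), (90, 90), (60, 60)]
        image = _image(_disk_image((128, 128), centers, radius=10))
        params = DetectionParams(threshold_mode="fixed", threshold_value=100,
                                 median_radius=0, min_area=50)
        dets = detect_macrophages(image, params)
        assert len(dets) == 5
        expected = lattice_disk_count(10)
        for det in dets:
            assert det.area_px == expected

    def test_disk_on_tile_boundary_matches_untiled_run(self):
        image = _image(_disk_image((256, 256), [(128, 128)], radius=12))
        tiled = DetectionParams(threshold_mode="fixed", threshold_value=100,
                                tile_size=128)
        untiled = DetectionParams(threshold_mode="fixed", threshold_value=100,
                                  tile_size=256)
        det_t = detect_macrophages(image, tiled)
        det_u = detect_macrophages(image, untiled)
        assert len(det_t) == len(det_u) == 1
        assert det_t[0].offset == det_u[0].offset
        np.testing.assert_array_equal(det_t[0].mask, det_u[0].mask)

    def test_annulus_detected_with_filled_area(self):
        arr = np.full((64, 64), 10.0)
        rr, cc = np.mgrid[0:64, 0:64]
        d2 = (rr - 32) ** 2 + (cc - 32) ** 2
        arr[(d2 <= 15 ** 2) & (d2 >= 9 ** 2)] = 200.0
        params = DetectionParams(threshold_mode="fixed", threshold_value=100,
                                 median_radius=0, min_area=10)
        dets = detect_macrophages(_image(arr), params)
        assert len(dets) == 1
        assert dets[0].area_px == lattice_disk_count(15)

    def test_min_area_boundary_is_inclusive(self):
        arr = np.full((64, 64), 0.0)
        arr[5:10, 5:14] = 200.0     # 5 x 9 = 45 px: below min_area 46
        arr[30:32, 30:53] = 200.0   # 2 x 23 = 46 px: exactly min_area
        params = DetectionParams(threshold_mode="fixed", threshold_value=100,
                                 median_radius=0, min_area=46,
                                 fill_holes=False)
        dets = detect_macrophages(_image(arr), params)
        assert len(dets) == 1
        assert dets[0].area_px == 46

    def test_border_touching_cells_flagged_not_dropped(self):
        arr = np.full((64, 64), 10.0)
        arr[0:12, 20:40] = 200.0
        params = DetectionParams(threshold_mode="fixed", threshold_value=100,
                                 median_radius=0, min_area=10)
        dets = detect_macrophages(_image(arr), params)
        assert len(dets) == 1 and dets[0].touches_border

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(tile_size=4, median_radius=2)
        with pytest.raises(ValueError):
            DetectionParams(min_area=0)
        with pytest.raises(ValueError):
            DetectionParams(threshold_mode="fixed", threshold_value=None)


class TestDetectionInvariants:
    @pytest.mark.parametrize("mode,value", [("fixed", 100.0),
                                            ("global-otsu", None)])
    def test_tiling_invariance(self, noisy_tissue, mode, value):
        """Detections are identical for any tile size under fixed or
        global-Otsu thresholding."""
        _, image, _, _, _ = noisy_tissue
        reference = None
        for tile_size in (64, 128, 256, max(image.shape)):
            params = DetectionParams(tile_size=tile_size, threshold_mode=mode,
                                     threshold_value=value)
            labels = detections_to_label_image(
                detect_macrophages(image, params), image.shape)
            if reference is None:
                reference = labels
            else:
                np.testing.assert_array_equal(labels, reference)

    def test_masks_disjoint_and_cover_filtered_foreground(self, noisy_tissue):
        _, image, _, _, _ = noisy_tissue
        params = DetectionParams()
        dets = detect_macrophages(image, params)
        cover = np.zeros(image.shape, dtype=int)
        for det in dets:
            r0, c0 = det.offset
            h, w = det.mask.shape
            cover[r0:r0 + h, c0:c0 + w] += det.mask
        assert cover.max() <= 1  # pairwise disjoint
        assert cover.sum() == sum(d.area_px for d in dets)

    def test_min_area_monotonicity(self, noisy_tissue):
        _, image, _, _, _ = noisy_tissue
        counts = [len(detect_macrophages(
            image, DetectionParams(min_area=a))) for a in (50, 150, 400)]
        assert counts == sorted(counts, reverse=True)

    def test_fixed_threshold_monotonicity(self, noisy_tissue):
        _, image, _, _, _ = noisy_tissue
        areas = []
        for t in (50.0, 120.0, 190.0):
            dets = detect_macrophages(image, DetectionParams(
                threshold_mode="fixed", threshold_value=t, min_area=1))
            areas.append(sum(d.area_px for d in dets))
        assert areas == sorted(areas, reverse=True)

    @given(hnp.arrays(bool, (24, 24),
                      elements=st.booleans()))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_hole_fill_idempotent(self, binary):
        once = fill_holes(binary, 8)
        np.testing.assert_array_equal(fill_holes(once, 8), once)
        assert (once | binary).sum() == once.sum()  # extensive
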
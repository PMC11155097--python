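"""Breast/lateral masks, Hessian vesselness, cleaning, detection metrics."""

import logging

import numpy as np
import pytest
from scipy import ndimage

from mipradiomics.errors import ContractError, SegmentationError
from mipradiomics.imaging_io import BinaryMask, MaskRole, MIPImage
from mipradiomics.synthetic_data import degrade_vessel_mask
from mipradiomics.vessel_segmentation import (
    DetectionMetrics,
    VesselCleanConfig,
    VesselnessMap,
    VesselnessParams,
    binarize_and_clean,
    detection_metrics,
    hessian_vesselness,
    lateral_breast_mask,
    remove_tumor_overlap,
    segment_breast,
)


def _dice(a, b):
    return 2 * np.sum(a & b) / (np.sum(a) + np.sum(b))


def _bar_image(shape=(64, 64), width=3, value=100.0, horizontal=True):
    img = np.zeros(shape)
    mid = shape[0] // 2
    half = width // 2
    if horizontal:
        img[mid - half : mid - half + width, 8:-8] = value
    else:
        img[8:-8, mid - half : mid - half + width] = value
    return img


class TestSegmentBreast:
    def test_recovers_phantom_breast(self, phantom):
        mask = segment_breast(phantom.image)
        assert _dice(mask.pixels, phantom.breast_mask_gt.pixels) > 0.90

    def test_constant_image_rejected(self):
        with pytest.raises(SegmentationError):
            segment_breast(MIPImage(np.full((32, 32), 7.0)))

    def test_full_frame_threshold_falls_back_to_border_policy(self, caplog, monkeypatch):
        import mipradiomics.vessel_segmentation as vs

        monkeypatch.setattr(vs, "threshold_otsu", lambda x: -1.0)
        img = MIPImage(np.abs(np.random.default_rng(0).normal(50, 5, (32, 32))))
        with caplog.at_level(logging.WARNING):
            mask = segment_breast(img)
        assert mask.pixels[1:-1, 1:-1].all() and not mask.pixels[0].any()


class TestLateralBreastMask:
    def test_left_and_right_tumor_select_matching_half(self):
        breast = BinaryMask(np.ones((20, 40), bool), role=MaskRole.BREAST)
        for col, left in ((10, True), (30, False)):
            tumor = np.zeros((20, 40), bool)
            tumor[10, col] = True
            out = lateral_breast_mask(breast, BinaryMask(tumor, role=MaskRole.TUMOR))
            half = out.pixels[:, :20] if left else out.pixels[:, 20:]
            other = out.pixels[:, 20:] if left else out.pixels[:, :20]
            assert half.all() and not other.any()

    def test_every_retained_pixel_on_tumor_side(self, phantom):
        breast = segment_breast(phantom.image)
        out = lateral_breast_mask(breast, phantom.tumor_mask_gt)
        w = out.shape[1]
        centroid = np.mean(np.nonzero(phantom.tumor_mask_gt.pixels)[1])
        cols = np.nonzero(out.pixels)[1]
        if centroid < w / 2:
            assert (cols < w / 2).all()
        else:
            assert (cols >= w / 2).all()

    def test_midline_centroid_goes_left_with_warning(self, caplog):
        breast = BinaryMask(np.ones((10, 10), bool), role=MaskRole.BREAST)
        tumor = np.zeros((10, 10), bool)
        tumor[5, 4:6] = True  # centroid at column 4.5... make it exactly 5.0
        tumor[:] = False
        tumor[5, 5] = True
        with caplog.at_level(logging.WARNING):
            out = lateral_breast_mask(breast, BinaryMask(tumor, role=MaskRole.TUMOR))
        assert out.pixels[:, :5].all() and not out.pixels[:, 5:].any()
        assert any("midline" in r.message for r in caplog.records)

    def test_empty_tumor_rejected(self):
        breast = BinaryMask(np.ones((10, 10), bool), role=MaskRole.BREAST)
        with pytest.raises(ContractError):
            lateral_breast_mask(breast, BinaryMask(np.zeros((10, 10), bool)))


class TestHessianVesselness:
    def test_constant_image_has_zero_response(self):
        vmap = hessian_vesselness(MIPImage(np.full((32, 32), 40.0)))
        assert np.all(vmap.values == 0)

    def test_response_in_unit_interval(self, phantom):
        vmap = hessian_vesselness(phantom.image)
        assert vmap.values.min() >= 0 and vmap.values.max() <= 1

    def test_invariant_to_constant_offset(self, small_phantom):
        a = hessian_vesselness(small_phantom.image)
        b = hessian_vesselness(MIPImage(small_phantom.image.pixels + 500.0))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_bar_centerline_prefers_matching_scale_and_beats_background(self):
        img = MIPImage(_bar_image(width=3))
        fine = hessian_vesselness(img, VesselnessParams(scales=(1.5,)))
        coarse = hessian_vesselness(img, VesselnessParams(scales=(6.0,)))
        mid = img.pixels.shape[0] // 2
        center_fine = fine.values[mid, 20:-20]
        assert np.all(center_fine > coarse.values[mid, 20:-20])
        background = fine.values[5:10, 20:-20].max()
        assert center_fine.min() >= 10 * max(background, 1e-12)

    def test_blob_interior_suppressed_relative_to_bar(self):
        yy, xx = np.mgrid[:80, :80]
        disc = ((yy - 40) ** 2 + (xx - 40) ** 2 <= 30**2) * 100.0
        v_disc = hessian_vesselness(MIPImage(disc))
        v_bar = hessian_vesselness(MIPImage(_bar_image(width=3)))
        mid = 32
        bar_center = v_bar.values[mid, 20:-20].mean()
        disc_interior = v_disc.values[30:50, 30:50].mean()
        assert disc_interior < bar_center

    def test_rotation_robustness_45_degrees(self):
        size = 81
        img_axis = np.zeros((size, size))
        img_axis[40 - 1 : 40 + 2, 10:-10] = 100.0
        img_diag = np.zeros((size, size))
        for t in range(12, size - 12):
            img_diag[t - 1 : t + 2, t] = 100.0  # 45-degree bar, ~3 px wide
        va = hessian_vesselness(MIPImage(img_axis))
        vd = hessian_vesselness(MIPImage(img_diag))
        resp_axis = va.values[40, 25:-25].mean()
        diag_idx = np.arange(25, size - 25)
        resp_diag = vd.values[diag_idx, diag_idx].mean()
        assert abs(resp_diag - resp_axis) <= 0.25 * resp_axis

    def test_scale_argmax_monotone_in_tube_radius(self):
        best = []
        for radius in (1, 2, 3):
            img = MIPImage(_bar_image((64, 64), width=2 * radius + 1))
            vmap = hessian_vesselness(img)
            best.append(vmap.best_scale[32, 20:-20].mean())
        assert best[0] <= best[1] <= best[2]
        assert best[2] > best[0]

    def test_nonfinite_pixels_rejected(self):
        arr = np.ones((16, 16))
        mip = MIPImage(arr)
        mip.pixels[3, 3] = np.inf  # bypass constructor check deliberately
        with pytest.raises(ContractError):
            hessian_vesselness(mip)

    def test_params_invariants(self):
        with pytest.raises(ContractError):
            VesselnessParams(scales=())
        with pytest.raises(ContractError):
            VesselnessParams(scales=(3.0, 1.0, 2.0))
        with pytest.raises(ContractError):
            VesselnessParams(beta=-0.5)

    def test_qualitative_agreement_with_reference_filter(self, small_phantom):
        """Independent cross-check: scikit-image's Frangi filter should rank
        vessel pixels above background pixels in the same way."""
        from skimage.filters import frangi

        ours = hessian_vesselness(small_phantom.image).values
        ref = frangi(small_phantom.image.pixels, sigmas=(1, 2, 3, 4, 5, 6), black_ridges=False)
        vessel = small_phantom.vessel_mask_gt.pixels
        background = small_phantom.breast_mask_gt.pixels & ~vessel & ~small_phantom.tumor_mask_gt.pixels
        assert ours[vessel].mean() > 5 * ours[background].mean()
        assert ref[vessel].mean() > 5 * ref[background].mean()


class TestBinarizeAndClean:
    def test_zero_vesselness_gives_empty_mask_with_warning(self, caplog):
        vmap = VesselnessMap(np.zeros((32, 32)), (1.0,), np.ones((32, 32)))
        lateral = BinaryMask(np.ones((32, 32), bool), role=MaskRole.LATERAL_BREAST)
        with caplog.at_level(logging.WARNING):
            out = binarize_and_clean(vmap, lateral)
        assert out.is_empty

    def test_phantom_vessels_recovered(self, phantom):
        breast = segment_breast(phantom.image)
        lateral = lateral_breast_mask(breast, phantom.tumor_mask_gt)
        vmap = hessian_vesselness(phantom.image)
        vessel = binarize_and_clean(vmap, lateral)
        assert _dice(vessel.pixels, phantom.vessel_mask_gt.pixels) > 0.6
        det = detection_metrics(vessel, phantom.vessel_mask_gt)
        assert det.correct_rate > 80.0

    def test_small_gap_closed_into_single_component(self):
        tube = np.zeros((40, 60), bool)
        tube[19:22, 5:28] = True
        tube[19:22, 30:55] = True  # 2-px gap at columns 28-29
        vmap = VesselnessMap(tube.astype(float), (1.0,), np.ones(tube.shape))
        lateral = BinaryMask(np.ones(tube.shape, bool), role=MaskRole.LATERAL_BREAST)
        out = binarize_and_clean(vmap, lateral, VesselCleanConfig(threshold=0.5))
        _, n = ndimage.label(out.pixels, structure=np.ones((3, 3)))
        assert n == 1

    def test_empty_lateral_mask_rejected(self):
        vmap = VesselnessMap(np.ones((8, 8)), (1.0,), np.ones((8, 8)))
        with pytest.raises(ContractError):
            binarize_and_clean(vmap, BinaryMask(np.zeros((8, 8), bool)))


class TestRemoveTumorOverlap:
    def test_disjoint_inputs_unchanged(self):
        tumor = np.zeros((20, 20), bool)
        tumor[2:6, 2:6] = True
        vessel = np.zeros((20, 20), bool)
        vessel[10:12, :] = True
        t, v = remove_tumor_overlap(BinaryMask(tumor), BinaryMask(vessel, role=MaskRole.VESSEL))
        np.testing.assert_array_equal(t.pixels, tumor)
        np.testing.assert_array_equal(v.pixels, vessel)

    def test_overlap_erased_from_tumor_only(self):
        tumor = np.zeros((20, 20), bool)
        tumor[5:15, 5:15] = True  # 100 px
        vessel = np.zeros((20, 20), bool)
        vessel[9, 5:15] = True  # crosses 10 tumor px
        t, v = remove_tumor_overlap(BinaryMask(tumor), BinaryMask(vessel, role=MaskRole.VESSEL))
        assert t.count == 90
        np.testing.assert_array_equal(v.pixels, vessel)

    def test_outputs_always_disjoint(self, rng):
        for _ in range(20):
            tumor = rng.random((16, 16)) > 0.4
            vessel = rng.random((16, 16)) > 0.6
            tumor[0, 0], vessel[0, 0] = True, False  # keep tumor non-empty
            t, v = remove_tumor_overlap(
                BinaryMask(tumor), BinaryMask(vessel, role=MaskRole.VESSEL)
            )
            assert not np.any(t.pixels & v.pixels)

    def test_fully_covered_tumor_rejected(self):
        full = BinaryMask(np.ones((8, 8), bool))
        with pytest.raises(ContractError):
            remove_tumor_overlap(full, BinaryMask(np.ones((8, 8), bool), role=MaskRole.VESSEL))


def _parallel_tubes(n=10, shape=(140, 140)):
    mask = np.zeros(shape, bool)
    for k in range(n):
        row = 10 + 13 * k
        mask[row : row + 3, 15:125] = True
    return BinaryMask(mask, role=MaskRole.VESSEL)


class TestDetectionMetrics:
    def test_perfect_prediction(self, phantom):
        det = detection_metrics(phantom.vessel_mask_gt, phantom.vessel_mask_gt)
        assert (det.correct_rate, det.incorrect_rate, det.missed_rate) == (100.0, 0.0, 0.0)

    def test_empty_prediction_convention(self, phantom):
        empty = BinaryMask(np.zeros(phantom.vessel_mask_gt.shape, bool), role=MaskRole.VESSEL)
        det = detection_metrics(empty, phantom.vessel_mask_gt)
        assert (det.correct_rate, det.incorrect_rate, det.missed_rate) == (0.0, 0.0, 100.0)

    def test_designed_degradation_reproduces_rates(self):
        gt = _parallel_tubes(10)
        pred = degrade_vessel_mask(gt, miss_fraction=0.1, spurious_count=2, seed=3)
        det = detection_metrics(pred, gt)
        assert det.n_gt_segments == 10
        assert det.correct_rate == pytest.approx(90.0)
        assert det.missed_rate == pytest.approx(10.0)
        assert det.n_pred_segments == 11
        assert det.incorrect_rate == pytest.approx(100.0 * 2 / 11)

    def test_correct_plus_missed_is_always_100(self, rng):
        gt = _parallel_tubes(7)
        for seed in range(5):
            pred = degrade_vessel_mask(gt, miss_fraction=rng.uniform(0, 0.5), spurious_count=int(rng.integers(0, 4)), seed=seed)
            det = detection_metrics(pred, gt)
            assert det.correct_rate + det.missed_rate == pytest.approx(100.0)

    def test_empty_reference_rejected(self):
        empty = BinaryMask(np.zeros((8, 8), bool), role=MaskRole.VESSEL)
        with pytest.raises(ContractError):
            detection_metrics(empty, empty)

    def test_rates_validated(self):
        with pytest.raises(ContractError):
            DetectionMetrics(80.0, 0.0, 30.0, 10, 10)
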
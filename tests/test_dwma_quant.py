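import numpy as np
import pytest
from scipy import ndimage

from dwma.atlas import WM
from dwma.dwma_quant import (
    DWMAConfig,
    DWMADetector,
    QuantError,
    centrum_semiovale_mask,
    cerebral_stats,
    detect_dwma,
    normalized_dwma,
    top_slice,
)
from dwma.tissue_seg import T_GM, T_WM, TissueSegmentation
from dwma.volume import Volume, affine_from_voxel_dims


def _seg_from_labels(labels, voxel_dims=(0.93, 0.93, 1.0)):
    """One-hot segmentation built from known labels (codes 1,2,3)."""
    labels = np.asarray(labels)
    mask = labels > 0
    post = np.zeros(labels.shape + (3,))
    for t in range(3):
        post[..., t] = labels == t + 1
    return TissueSegmentation(
        posteriors=post, mask=mask, class_means={}, class_sds={},
        n_iterations=1, converged=True, voxel_dims=voxel_dims,
        log_likelihoods=np.zeros(1),
    )


class TestCerebralStats:
    def test_constant_intensity_gives_zero_sd(self):
        labels = np.full((6, 6, 6), 3)
        seg = _seg_from_labels(labels)
        vol = Volume(np.full((6, 6, 6), 42.0), np.eye(4))
        mu, sd = cerebral_stats(vol, seg)
        assert (mu, sd) == (42.0, 0.0)

    def test_matches_brute_force(self, small_pipeline):
        seg = small_pipeline.segmentation
        vol = small_pipeline.normalized
        mu, sd = cerebral_stats(vol, seg, 0.95)
        post = seg.posteriors
        elig = (post[..., T_GM] >= 0.95) | (post[..., T_WM] >= 0.95)
        vals = [vol.data[i] for i in zip(*np.nonzero(elig))]
        assert mu == pytest.approx(np.mean(vals), rel=1e-12)
        assert sd == pytest.approx(np.std(vals), rel=1e-12)

    def test_raising_tau_shrinks_eligible_set(self, small_pipeline):
        post = small_pipeline.segmentation.posteriors
        e95 = (post[..., T_GM] >= 0.95) | (post[..., T_WM] >= 0.95)
        e99 = (post[..., T_GM] >= 0.99) | (post[..., T_WM] >= 0.99)
        assert not (e99 & ~e95).any()

    def test_too_few_eligible_rejected(self):
        labels = np.ones((4, 4, 4))  # all CSF
        seg = _seg_from_labels(labels)
        with pytest.raises(QuantError, match="membership"):
            cerebral_stats(Volume(np.zeros((4, 4, 4)), np.eye(4)), seg)


class TestCentrumSemiovale:
    def _toy(self):
        """WM slab with a ventricle block topping out at slice 5."""
        labels = np.zeros((20, 20, 12), dtype=int)
        labels[2:18, 2:18, :] = 3
        vent = np.zeros_like(labels, dtype=bool)
        vent[8:12, 8:12, 2:6] = True
        labels[vent] = 1
        return labels, vent

    def test_slices_above_ventricle_top(self):
        labels, vent = self._toy()
        seg = _seg_from_labels(labels)
        cfg = DWMAConfig(midline_exclusion_voxels=0, cs_erosion_voxels=0)
        mask = centrum_semiovale_mask(seg, vent, cfg)
        assert sorted(set(np.nonzero(mask)[2])) == [6, 7]

    def test_subset_of_wm(self, small_pipeline):
        from dwma.tissue_seg import hard_labels

        wm = hard_labels(small_pipeline.segmentation) == WM
        assert not (small_pipeline.cs_mask & ~wm).any()

    def test_matches_brute_force_reimplementation(self):
        labels, vent = self._toy()
        seg = _seg_from_labels(labels)
        cfg = DWMAConfig()
        mask = centrum_semiovale_mask(seg, vent, cfg)

        # independent reconstruction
        k = 5
        expect = np.zeros_like(vent)
        for z in (6, 7):
            sl = labels[:, :, z] == 3
            er = np.zeros_like(sl)
            for i in range(1, 19):
                for j in range(1, 19):
                    if sl[i, j] and sl[i - 1, j] and sl[i + 1, j] and sl[i, j - 1] and sl[i, j + 1]:
                        er[i, j] = True
            expect[:, :, z] = er
        mid = (labels.shape[0] - 1) / 2
        for x in range(labels.shape[0]):
            if abs(x - mid) <= cfg.midline_exclusion_voxels:
                expect[x, :, :] = False
        np.testing.assert_array_equal(mask, expect)

    def test_single_voxel_straggler_ignored(self):
        labels, vent = self._toy()
        vent2 = vent.copy()
        vent2[9, 9, 6] = True  # lone voxel one slice above the apex
        seg = _seg_from_labels(labels)
        cfg = DWMAConfig(midline_exclusion_voxels=0, cs_erosion_voxels=0)
        m1 = centrum_semiovale_mask(seg, vent, cfg)
        m2 = centrum_semiovale_mask(seg, vent2, cfg)
        np.testing.assert_array_equal(m1, m2)

    def test_window_beyond_grid_rejected(self):
        labels, vent = self._toy()
        vent[8:12, 8:12, :11] = True  # ventricle reaching slice 10 of 12
        seg = _seg_from_labels(labels)
        with pytest.raises(QuantError, match="exceed"):
            centrum_semiovale_mask(seg, vent, DWMAConfig())

    def test_top_slice_minimum_area(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[0:3, 0:3, 4] = True
        m[5, 5, 7] = True
        assert top_slice(m, min_voxels=5) == 4
        assert top_slice(m, min_voxels=1) == 7


class TestDetect:
    def test_huge_alpha_gives_empty_valid_result(self, small_pipeline):
        res = detect_dwma(
            small_pipeline.normalized,
            small_pipeline.segmentation,
            small_pipeline.cs_mask,
            DWMAConfig(alpha=10.0),
        )
        assert res.n_voxels == 0
        assert res.normalized_volume == 0.0

    def test_phantom_recovery(self, small_pipeline, small_phantom):
        _, _, truth = small_phantom
        res = small_pipeline.result
        t = truth.dwma_mask
        dice = 2 * (res.mask & t).sum() / (res.mask.sum() + t.sum())
        assert dice >= 0.80
        err = abs(res.volume_mm3 - truth.dwma_true_volume_mm3)
        assert err <= 0.15 * truth.dwma_true_volume_mm3

    def test_count_nonincreasing_in_alpha(self, small_pipeline):
        counts = [
            detect_dwma(
                small_pipeline.normalized,
                small_pipeline.segmentation,
                small_pipeline.cs_mask,
                DWMAConfig(alpha=a),
            ).n_voxels
            for a in (1.5, 1.8, 2.0)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_mask_nests_in_tau(self, small_pipeline):
        masks = [
            detect_dwma(
                small_pipeline.normalized,
                small_pipeline.segmentation,
                small_pipeline.cs_mask,
                DWMAConfig(membership_threshold=tau),
            ).mask
            for tau in (0.90, 0.95, 0.99)
        ]
        assert not (masks[1] & ~masks[0]).any()
        assert not (masks[2] & ~masks[1]).any()

    def test_volume_identity_exact(self, small_pipeline):
        res = small_pipeline.result
        vv = float(np.prod(small_pipeline.segmentation.voxel_dims))
        assert res.volume_mm3 == res.n_voxels * vv

    def test_small_components_removed(self):
        labels = np.full((20, 20, 10), 3)
        seg = _seg_from_labels(labels)
        data = np.full((20, 20, 10), 100.0)
        # one 2-voxel island and one 4-voxel island above threshold
        data[2, 2, 4] = data[2, 3, 4] = 500.0
        data[10, 10, 4] = data[10, 11, 4] = data[11, 10, 4] = data[11, 11, 4] = 500.0
        # break the constant background so sigma > 0
        rng = np.random.default_rng(0)
        data += rng.normal(0, 1.0, data.shape)
        vol = Volume(data, affine_from_voxel_dims((1, 1, 1)))
        cs = np.ones(data.shape, dtype=bool)
        res = detect_dwma(vol, seg, cs, DWMAConfig(alpha=3.0, min_component_voxels=3))
        assert res.n_voxels == 4
        assert res.mask[10, 10, 4] and not res.mask[2, 2, 4]

    def test_detection_invariant_to_affine_intensity(self, small_pipeline):
        v = small_pipeline.normalized
        seg = small_pipeline.segmentation
        scaled = v.with_data(2.5 * v.data + 17.0)
        r1 = detect_dwma(v, seg, small_pipeline.cs_mask)
        r2 = detect_dwma(scaled, seg, small_pipeline.cs_mask)
        np.testing.assert_array_equal(r1.mask, r2.mask)


class TestNormalizedDWMA:
    def test_arithmetic(self):
        from dwma.dwma_quant import DWMAResult

        res = DWMAResult(
            mask=np.zeros((1, 1, 1), bool), n_voxels=100, volume_mm3=86.49,
            wm_volume_mm3=86490.0, normalized_volume=0.001, cerebral_mean=0.0,
            cerebral_sd=1.0, threshold_used=0.0,
        )
        assert normalized_dwma(res) == pytest.approx(0.001)

    def test_zero_wm_volume_rejected(self):
        from dwma.dwma_quant import DWMAResult

        res = DWMAResult(
            mask=np.zeros((1, 1, 1), bool), n_voxels=0, volume_mm3=0.0,
            wm_volume_mm3=0.0, normalized_volume=0.0, cerebral_mean=0.0,
            cerebral_sd=1.0, threshold_used=0.0,
        )
        with pytest.raises(QuantError):
            normalized_dwma(res)

    def test_soft_close_to_hard_count_ratio_on_clean_seg(self, clean_atlas):
        """With one-hot posteriors the soft and hard denominators coincide."""
        labels = clean_atlas.argmax_labels()
        seg = _seg_from_labels(labels)
        from dwma.tissue_seg import tissue_volumes

        soft = tissue_volumes(seg)["wm"]
        hard = tissue_volumes(seg, hard=True)["wm"]
        assert soft == pytest.approx(hard, rel=1e-12)


class TestDetectorEstimator:
    def test_end_to_end_detector(self, small_pipeline, small_atlas):
        det = DWMADetector(alpha=1.8)
        res = det.detect(
            small_pipeline.normalized, small_pipeline.segmentation, small_atlas
        )
        assert res.n_voxels == small_pipeline.result.n_voxels
        np.testing.assert_array_equal(det.cs_mask_, small_pipeline.cs_mask)

    def test_invalid_config(self):
        with pytest.raises(QuantError):
            DWMAConfig(alpha=0.0)
        with pytest.raises(QuantError):
            DWMAConfig(min_component_voxels=0)
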
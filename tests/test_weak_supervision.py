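import numpy as np
import pandas as pd
import pytest

from pscml import nn
from pscml.weak_supervision import (
    CamResult,
    PatchCNN,
    build_patch_dataset,
    gradcam,
    mask_from_fluorescence,
    rank_wells,
    segmentation_metrics,
)
from pscml.well_io import MASK_BLACK, MASK_DARK_GRAY, MASK_LIGHT_GRAY, RegionMask, WellImage


def well_with_mask(frac_dark: float, size=64):
    labels = np.full((size, size), MASK_BLACK, np.uint8)
    n_dark = int(frac_dark * size * size)
    labels.ravel()[:n_dark] = MASK_DARK_GRAY
    return WellImage(np.random.default_rng(0).random((size, size))), RegionMask(labels)


class TestPatchLabeling:
    def test_thirty_five_percent_dark_is_positive(self):
        img, mask = well_with_mask(0.35)
        ds = build_patch_dataset([img], [mask], patch=64, overlap=0.5)
        assert list(ds.labels) == [1]

    def test_all_black_is_negative(self):
        img, mask = well_with_mask(0.0)
        ds = build_patch_dataset([img], [mask], patch=64, overlap=0.5)
        assert list(ds.labels) == [0]

    def test_ten_percent_dark_discarded(self):
        img, mask = well_with_mask(0.10)
        ds = build_patch_dataset([img], [mask], patch=64, overlap=0.5)
        assert len(ds) == 0

    def test_light_gray_blocks_negative_label(self):
        img, mask = well_with_mask(0.0)
        labels = mask.labels.copy()
        labels[0, 0] = MASK_LIGHT_GRAY
        ds = build_patch_dataset([img], [RegionMask(labels)], patch=64, overlap=0.5)
        assert len(ds) == 0  # neither positive nor all-black

    def test_de_variant_20_percent_rule(self):
        img, _ = well_with_mask(0.0)
        binary = np.zeros((64, 64), np.uint8)
        binary.ravel()[: int(0.22 * 64 * 64)] = 255
        ds = build_patch_dataset(
            [img], [binary], patch=64, overlap=0.5, positive_frac=0.20, positive_code=255
        )
        assert list(ds.labels) == [1]

    def test_misaligned_shapes_rejected(self):
        img, _ = well_with_mask(0.3)
        with pytest.raises(ValueError, match="differ"):
            build_patch_dataset([img], [np.zeros((32, 32), np.uint8)], 32, 0.5)


class TestFluorescenceMask:
    def test_zero_fluorescence_empty_mask(self):
        assert not mask_from_fluorescence(np.zeros((32, 32))).any()

    def test_nearby_dots_merged_by_closing(self):
        from skimage.measure import label

        img = np.zeros((48, 48))
        img[18:24, 16:20] = 1.0
        img[18:24, 24:28] = 1.0  # gap 4 < 2 * radius
        mask = mask_from_fluorescence(img, threshold=0.5, closing_radius=5)
        assert label(mask).max() == 1
        far = np.zeros((48, 48))
        far[18:24, 16:20] = 1.0
        far[18:24, 40:44] = 1.0  # gap 16 > 2 * radius stays separate
        assert label(mask_from_fluorescence(far, 0.5, 5)).max() == 2

    def test_closing_idempotent(self):
        rng = np.random.default_rng(1)
        img = (rng.random((48, 48)) > 0.95).astype(float)
        once = mask_from_fluorescence(img, closing_radius=3)
        twice = mask_from_fluorescence(once.astype(float), threshold=0.5, closing_radius=3)
        np.testing.assert_array_equal(once, twice)


class TestGradCam:
    def _tiny_model(self):
        model = PatchCNN(channels=(2, 2, 2), seed=4)
        return model

    def test_heatmap_matches_explicit_loop_oracle(self):
        model = self._tiny_model()
        rng = np.random.default_rng(0)
        patch = rng.random((32, 32))
        # force a positive prediction so the cam is computed
        model.head.W[:] = 0.0
        model.head.W[:, 1] = 1.0
        model.head.b[:] = [0.0, 1.0]

        A, dA = model.activations_and_gradient(patch, class_index=1)
        # oracle: alpha_k = (1/Z) sum_ij dY/dA computed with explicit loops,
        # and dY/dA_kij = W[k, positive] / Z for a GAP -> linear head
        Z = A.shape[1] * A.shape[2]
        alpha_oracle = np.zeros(A.shape[0])
        for k in range(A.shape[0]):
            for i in range(A.shape[1]):
                for j in range(A.shape[2]):
                    alpha_oracle[k] += model.head.W[k, 1] / Z
            alpha_oracle[k] /= Z
        cam_oracle = np.zeros(A.shape[1:])
        for k in range(A.shape[0]):
            cam_oracle += alpha_oracle[k] * A[k]
        cam_oracle = np.maximum(cam_oracle, 0.0)

        alpha = dA.mean(axis=(1, 2))
        np.testing.assert_allclose(alpha, alpha_oracle, atol=1e-6)
        cam = np.maximum((alpha[:, None, None] * A).sum(axis=0), 0.0)
        np.testing.assert_allclose(cam, cam_oracle, atol=1e-6)

    def test_negative_prediction_gives_all_zero_map(self):
        model = self._tiny_model()
        model.head.b[:] = [10.0, -10.0]  # force negative class
        result = gradcam(model, np.random.default_rng(1).random((32, 32)))
        assert not result.heatmap.any()
        assert not result.binary.any()

    def test_binarization_threshold_default_ten(self):
        model = self._tiny_model()
        model.head.b[:] = [-10.0, 10.0]  # force positive class
        result = gradcam(model, np.random.default_rng(2).random((32, 32)))
        if result.normalized8.max() > 0:
            np.testing.assert_array_equal(result.binary, result.normalized8 > 10)

    def test_normalized_map_peaks_at_255(self):
        model = self._tiny_model()
        model.head.b[:] = [-10.0, 10.0]
        result = gradcam(model, np.random.default_rng(3).random((32, 32)))
        if result.heatmap.any():
            assert result.normalized8.max() == pytest.approx(255.0)


class TestSegmentationMetrics:
    def test_hand_worked_confusion_matrix(self):
        # TP=50, FP=10, FN=40, TN=100 on a 200-pixel image
        pred = np.zeros(200, bool)
        gt = np.zeros(200, np.uint8)
        pred[:50] = True; gt[:50] = MASK_DARK_GRAY          # TP
        pred[50:60] = True                                   # FP
        gt[60:100] = MASK_LIGHT_GRAY                         # FN
        m = segmentation_metrics(pred.reshape(10, 20), gt.reshape(10, 20), mode="cpc")
        assert m["precision"] == pytest.approx(5 / 6)
        assert m["recall"] == pytest.approx(5 / 9)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["iou"] == pytest.approx(0.5)
        assert m["specificity"] == pytest.approx(10 / 11)
        assert m["accuracy"] == pytest.approx(0.75)

    def test_perfect_prediction_all_ones(self):
        gt = np.zeros((8, 8), np.uint8)
        gt[:4] = MASK_DARK_GRAY
        m = segmentation_metrics(gt == MASK_DARK_GRAY, gt, mode="cpc")
        for key in ("accuracy", "precision", "recall", "f1", "specificity", "iou"):
            assert m[key] == 1.0

    def test_f1_iou_identity_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            pred = rng.random((8, 8)) > rng.random()
            gt = np.where(rng.random((8, 8)) > rng.random(), MASK_DARK_GRAY, 0).astype(np.uint8)
            m = segmentation_metrics(pred, gt, mode="cpc")
            if m["iou"] > 0:
                assert m["f1"] == pytest.approx(2 * m["iou"] / (1 + m["iou"]))
            prev = (gt > 0).mean()
            lo, hi = sorted([m["recall"], m["specificity"]])
            blended = prev * m["recall"] + (1 - prev) * m["specificity"]
            assert lo - 1e-9 <= m["accuracy"] <= hi + 1e-9
            assert m["accuracy"] == pytest.approx(blended)

    def test_degenerate_ground_truth_flagged(self):
        gt = np.full((8, 8), MASK_DARK_GRAY, np.uint8)
        assert segmentation_metrics(np.ones((8, 8), bool), gt, mode="cpc")["discarded"]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            segmentation_metrics(np.ones((4, 4), bool), np.zeros((5, 5), np.uint8))


class TestRanking:
    def _table(self):
        return pd.DataFrame(
            {
                "well_id": ["w1", "w2", "w3", "w4", "nc"],
                "fraction": [0.5, 0.45, 0.45, 0.1, 0.02],
                "control": ["", "", "", "", "negative"],
            }
        )

    def test_descending_rank_with_id_tiebreak(self):
        out = rank_wells(self._table(), top_k=2)
        ranked = out[out["rank"].notna()].sort_values("rank")
        assert list(ranked.well_id) == ["w1", "w2", "w3", "w4"]  # tie w2 < w3 by id

    def test_top_k_and_threshold_flags(self):
        out = rank_wells(self._table(), top_k=2, candidate_threshold=0.40)
        by_id = out.set_index("well_id")
        assert bool(by_id.loc["w1", "top_k"]) and bool(by_id.loc["w2", "top_k"])
        assert not by_id.loc["w3", "top_k"]
        assert set(out[out.above_threshold].well_id) == {"w1", "w2", "w3"}

    def test_controls_carried_through_unranked(self):
        out = rank_wells(self._table())
        assert np.isnan(out.set_index("well_id").loc["nc", "rank"])

    def test_fraction_bounds_enforced(self):
        bad = self._table()
        bad.loc[0, "fraction"] = 1.2
        with pytest.raises(ValueError, match="0, 1"):
            rank_wells(bad)
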
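import numpy as np
import pytest
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from pscml.colony_model import (
    N_COLONY_FEATURES,
    colony_feature_vector,
    fit_forest,
    predict_efficiency,
    shape_stats,
    spacing,
)


def disc_mask(size=128, radius=40):
    yy, xx = np.mgrid[:size, :size]
    return (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2


class TestShapeStats:
    def test_filled_disc_is_nearly_circular(self):
        stats = shape_stats(disc_mask())
        assert stats["Solidity"] >= 0.98
        assert stats["Circularity"] == pytest.approx(1.0, rel=0.05)
        assert stats["StdCCD"] / stats["MeanCCD"] <= 0.05

    def test_filled_square_is_exactly_solid(self):
        mask = np.zeros((64, 64), bool)
        mask[10:50, 10:50] = True
        assert shape_stats(mask)["Solidity"] == pytest.approx(1.0, abs=1e-9)

    def test_plus_sign_against_polygon_oracle(self):
        # plus shape: 3s x 3s cross of arm width s
        s = 30
        verts = [
            (s, 0), (2 * s, 0), (2 * s, s), (3 * s, s), (3 * s, 2 * s),
            (2 * s, 2 * s), (2 * s, 3 * s), (s, 3 * s), (s, 2 * s),
            (0, 2 * s), (0, s), (s, s),
        ]
        poly = Polygon(verts)
        mask = np.zeros((3 * s + 20, 3 * s + 20), bool)
        rr, cc = draw_polygon([v[1] + 10 for v in verts], [v[0] + 10 for v in verts])
        mask[rr, cc] = True
        stats = shape_stats(mask)
        hull = poly.convex_hull
        solidity_oracle = poly.area / hull.area
        convexity_oracle = hull.length / poly.length
        assert stats["Solidity"] == pytest.approx(solidity_oracle, rel=0.05)
        assert stats["Convexity"] == pytest.approx(convexity_oracle, rel=0.05)
        assert stats["Solidity"] < 1 and stats["Convexity"] < 1

    def test_ccd_ordering_invariants(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = np.zeros((64, 64), bool)
            r, c = rng.integers(10, 40, 2)
            h, w = rng.integers(8, 20, 2)
            mask[r : r + h, c : c + w] = True
            stats = shape_stats(mask)
            assert stats["MinCCD"] <= stats["MeanCCD"] <= stats["MaxCCD"]
            assert stats["MinMaxCCD"] == pytest.approx(stats["MinCCD"] / stats["MaxCCD"])

    def test_circularity_isoperimetric_bound(self):
        rng = np.random.default_rng(1)
        from scipy import ndimage as ndi

        for _ in range(30):
            blob = ndi.gaussian_filter(rng.standard_normal((64, 64)), 4) > 0
            if blob.sum() < 60:
                continue
            assert shape_stats(blob)["Circularity"] <= 1.05

    def test_empty_mask_zeros_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            stats = shape_stats(np.zeros((32, 32), bool))
        assert all(v == 0 for v in stats.values())


class TestSpacing:
    def test_half_planes_with_band_recover_half_width(self):
        w = 12
        mask = np.ones((100, 100), bool)
        mask[:, 50 - w : 50 + w] = False  # 2w-wide empty band
        assert spacing(mask) == pytest.approx(w, rel=0.10)

    def test_single_free_pixel_small_spacing(self):
        mask = np.ones((32, 32), bool)
        mask[16, 16] = False
        assert spacing(mask) <= 1.5

    def test_transpose_invariant(self):
        rng = np.random.default_rng(2)
        from scipy import ndimage as ndi

        mask = ndi.gaussian_filter(rng.standard_normal((80, 80)), 6) > 0
        assert spacing(mask) == pytest.approx(spacing(mask.T), rel=0.05)

    def test_degenerate_masks_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert spacing(np.ones((16, 16), bool)) == 0.0
            assert spacing(np.zeros((16, 16), bool)) == 0.0


class TestColonyFeatureVector:
    def test_length_343(self, codebooks, well_triplet):
        sift, orb = codebooks
        feats = colony_feature_vector(well_triplet[0], sift, orb)
        assert feats.vector.shape == (N_COLONY_FEATURES,) == (343,)

    def test_constant_image_texture_features_zero(self, codebooks):
        sift, orb = codebooks
        feats = colony_feature_vector(np.full((256, 256), 0.5), sift, orb).as_dict()
        assert feats["CellContrast"] == 0.0
        assert feats["TotalVariation"] == 0.0
        assert sum(feats[f"SIFT{i}"] for i in range(1, 257)) == 0
        assert sum(feats[f"ORB{i}"] for i in range(1, 65)) == 0

    def test_hu_moments_rotation_invariant(self, well_triplet):
        from skimage.measure import moments_central, moments_hu, moments_normalized

        px = well_triplet[0].pixels
        hu = moments_hu(moments_normalized(moments_central(px)))
        hu_rot = moments_hu(moments_normalized(moments_central(np.rot90(px))))
        np.testing.assert_allclose(hu, hu_rot, rtol=1e-3, atol=1e-12)

    def test_deterministic_given_fixed_codebooks(self, codebooks, well_triplet):
        sift, orb = codebooks
        a = colony_feature_vector(well_triplet[0], sift, orb).vector
        b = colony_feature_vector(well_triplet[0], sift, orb).vector
        np.testing.assert_array_equal(a, b)

    def test_missing_codebook_rejected(self, well_triplet):
        with pytest.raises(ValueError, match="codebook"):
            colony_feature_vector(well_triplet[0], None, None)


class TestForest:
    def _planted(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 12))
        y = np.clip(0.5 + 0.4 * X[:, 5] + 0.02 * rng.standard_normal(n), 0, 1)
        return X, y

    def test_planted_feature_ranks_first_in_importance(self):
        X, y = self._planted()
        _, imp = fit_forest(X, y, mode="importance")
        assert imp.argmax() == 5

    def test_importances_sum_to_one(self):
        X, y = self._planted(seed=1)
        _, imp = fit_forest(X, y, mode="prediction")
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_prediction_mode_uses_20_trees(self):
        X, y = self._planted(seed=2)
        model, _ = fit_forest(X, y, mode="prediction")
        assert model.n_estimators == 20

    def test_importance_mode_hyperparameters(self):
        X, y = self._planted(seed=3)
        model, _ = fit_forest(X, y, mode="importance")
        assert (model.n_estimators, model.max_depth, model.max_features) == (1000, 8, 15)

    def test_nan_features_rejected_naming_columns(self):
        X, y = self._planted()
        X[3, 7] = np.nan
        with pytest.raises(ValueError, match="7"):
            fit_forest(X, y)

    def test_training_data_refit_correlation(self):
        X, y = self._planted(n=120, seed=4)
        model, _ = fit_forest(X, y, mode="importance")
        pred = predict_efficiency(model, X)
        assert np.corrcoef(pred, y)[0, 1] >= 0.95

    def test_constant_target_constant_predictions(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 6))
        model, _ = fit_forest(X, np.full(40, 0.6))
        assert np.allclose(predict_efficiency(model, X), 0.6)

    def test_feature_mismatch_rejected(self):
        X, y = self._planted()
        model, _ = fit_forest(X, y)
        with pytest.raises(ValueError, match="mismatch"):
            predict_efficiency(model, X[:, :5])
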
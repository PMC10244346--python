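"""343-D morphological profiling of 0 h PSC colonies and efficiency forests.

The profile concatenates, in a fixed canonical order:

* 4 texture statistics of the cell-containing regions (local entropy at
  radius 5, brightness, contrast, total variation of the image),
* the 7 Hu invariant moments of the grayscale image,
* a 256-D SIFT and a 64-D ORB bag-of-keypoints histogram,
* colony-region statistics (area, circumference, their ratio, normalized by
  the image width as appropriate),
* area-weighted shape statistics per connected component (solidity,
  convexity, circularity; centroid-contour-distance max/min/ratio/mean/std),
* the inter-colony spacing (mean distance from the skeleton of the
  cell-free space to the nearest colony pixel).

A random forest regressor maps the profile to the line-normalized final
differentiation efficiency: 1000 trees of depth 8 with 15 features per split
when ranking feature importance, 20 trees when predicting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import find_contours, label as cc_label, moments_central, moments_hu, moments_normalized
from skimage.morphology import convex_hull_image, skeletonize

from pscml.features_local import Codebook, bag_of_keypoints
from pscml.features_stream import local_entropy_map, mask_contour_length
from pscml.well_io import WellImage
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)

ENTROPY_RADIUS = 5  # the colony profile uses a tighter neighborhood than streams
MIN_COMPONENT_AREA = 50  # specks below this are dropped before shape stats

COLONY_FEATURE_NAMES: tuple[str, ...] = (
    ("LocalEntropy", "CellBrightness", "CellContrast", "TotalVariation")
    + tuple(f"HuMoment{i}" for i in range(1, 8))
    + tuple(f"SIFT{i}" for i in range(1, 257))
    + tuple(f"ORB{i}" for i in range(1, 65))
    + ("Area", "Circumference", "ACRatio")
    + ("Solidity", "Convexity", "Circularity")
    + ("MaxCCD", "MinCCD", "MinMaxCCD", "MeanCCD", "StdCCD")
    + ("Spacing",)
)
N_COLONY_FEATURES = len(COLONY_FEATURE_NAMES)  # 343


@dataclass(frozen=True)
class ColonyFeatures:
    vector: np.ndarray
    names: tuple[str, ...] = COLONY_FEATURE_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=float))
        if self.vector.shape != (N_COLONY_FEATURES,):
            raise ValueError(f"colony feature vector must have length {N_COLONY_FEATURES}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.vector))


# ---------------------------------------------------------------------------
# shape statistics


def _component_shape(mask: np.ndarray) -> dict[str, float]:
    """Solidity, convexity, circularity and CCD stats of one component.

    Perimeters use the 4-direction Crofton estimator, which is nearly
    unbiased on smooth shapes (a rasterized disc's circularity stays within
    a few percent of 1, where raw marching-squares contours overshoot).
    """
    from skimage.measure import perimeter_crofton

    perimeter = float(perimeter_crofton(mask, directions=4))
    hull = convex_hull_image(mask)
    hull_perimeter = float(perimeter_crofton(hull, directions=4))
    area = float(mask.sum())
    hull_area = float(hull.sum())
    solidity = area / hull_area if hull_area else 0.0
    convexity = hull_perimeter / perimeter if perimeter else 0.0
    circularity = 4 * np.pi * area / perimeter**2 if perimeter else 0.0

    ys, xs = np.nonzero(mask)
    centroid = np.array([ys.mean(), xs.mean()])
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    points = np.vstack(contours) - 1.0  # undo padding offset
    ccd = np.linalg.norm(points - centroid, axis=1)
    return {
        "Solidity": solidity,
        "Convexity": convexity,
        "Circularity": circularity,
        "MaxCCD": float(ccd.max()),
        "MinCCD": float(ccd.min()),
        "MinMaxCCD": float(ccd.min() / ccd.max()) if ccd.max() else 0.0,
        "MeanCCD": float(ccd.mean()),
        "StdCCD": float(ccd.std()),
        "_area": area,
    }


SHAPE_KEYS = ("Solidity", "Convexity", "Circularity", "MaxCCD", "MinCCD", "MinMaxCCD", "MeanCCD", "StdCCD")


def shape_stats(mask: np.ndarray, min_area: int = MIN_COMPONENT_AREA) -> dict[str, float]:
    """Area-weighted component shape statistics of a binary colony mask.

    Components are 8-connected; components smaller than ``min_area`` pixels
    are treated as noise specks and dropped. An empty mask yields zeros with
    a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled = cc_label(mask, connectivity=2)
    per_component = []
    for region_id in range(1, labeled.max() + 1):
        comp = labeled == region_id
        if comp.sum() < min_area:
            continue
        per_component.append(_component_shape(comp))
    if not per_component:
        logger.warning("no colony components above %d px; shape stats set to 0", min_area)
        return {k: 0.0 for k in SHAPE_KEYS}
    weights = np.array([c["_area"] for c in per_component])
    weights = weights / weights.sum()
    return {
        k: float(sum(w * c[k] for w, c in zip(weights, per_component)))
        for k in SHAPE_KEYS
    }


def spacing(mask: np.ndarray) -> float:
    """Mean distance from the cell-free skeleton to the nearest colony pixel.

    The cell-free space between colonies is skeletonized (its medial axis);
    the value is the mean Euclidean distance-transform value of the colony
    mask sampled at the skeleton pixels. A full or empty mask yields 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.all() or not mask.any():
        logger.warning("mask is full or empty; spacing set to 0")
        return 0.0
    skeleton = skeletonize(~mask)
    if not skeleton.any():
        return 0.0
    dist_to_cells = ndi.distance_transform_edt(~mask)
    return float(dist_to_cells[skeleton].mean())


# ---------------------------------------------------------------------------
# the full 343-D profile


def colony_feature_vector(
    img: WellImage | np.ndarray,
    sift_codebook: Codebook,
    orb_codebook: Codebook,
    entropy_radius: int = ENTROPY_RADIUS,
    entropy_threshold: float = 3.0,
) -> ColonyFeatures:
    """Compute the 343-D morphological profile of one whole-well image.

    Requires fitted bag-of-keypoints codebooks with k = 256 (SIFT) and
    k = 64 (ORB); the codebooks' fitting images must be disjoint from the
    dataset the profile feeds.
    """
    if sift_codebook is None or orb_codebook is None:
        raise ValueError("both SIFT and ORB codebooks are required")
    if sift_codebook.k != 256 or orb_codebook.k != 64:
        raise ValueError("colony profile expects k=256 (SIFT) and k=64 (ORB) codebooks")
    px = img.pixels if isinstance(img, WellImage) else np.asarray(img, dtype=float)
    side = float(max(px.shape))

    ent = local_entropy_map(px, radius=entropy_radius)
    cells = ent >= entropy_threshold
    if cells.any():
        local_entropy = float(ent[cells].mean())
        brightness = float(px[cells].mean())
        contrast = float(px[cells].std())
    else:
        logger.warning("no cell-containing pixels; texture statistics set to 0")
        local_entropy = brightness = contrast = 0.0
    gy, gx = np.gradient(px)
    total_variation = float(np.mean(np.abs(gx) + np.abs(gy)))

    hu = moments_hu(moments_normalized(moments_central(px)))  # raw values, no log transform

    sift_hist = bag_of_keypoints(px, sift_codebook).astype(float)
    orb_hist = bag_of_keypoints(px, orb_codebook).astype(float)

    if cells.any():
        area = float(cells.mean())
        circumference = mask_contour_length(cells) / side
        ac_ratio = area / circumference if circumference else 0.0
    else:
        area = circumference = ac_ratio = 0.0

    shapes = shape_stats(cells)
    space = spacing(cells)

    vector = np.concatenate(
        [
            [local_entropy, brightness, contrast, total_variation],
            hu,
            sift_hist,
            orb_hist,
            [area, circumference, ac_ratio],
            [shapes["Solidity"], shapes["Convexity"], shapes["Circularity"]],
            [shapes["MaxCCD"], shapes["MinCCD"], shapes["MinMaxCCD"], shapes["MeanCCD"], shapes["StdCCD"]],
            [space],
        ]
    )
    return ColonyFeatures(vector=vector)


# ---------------------------------------------------------------------------
# random-forest efficiency model


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "prediction",
    seed: int = 0,
) -> tuple[RandomForestRegressor, np.ndarray]:
    """Random-forest regression of efficiency on colony profiles.

    ``importance`` mode uses 1000 trees of maximum depth 8 with 15 features
    considered per split (for stable feature rankings); ``prediction`` mode
    uses 20 trees with library defaults otherwise. Returns the fitted model
    and its impurity-based feature importances (summing to 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any():
        bad = np.unique(np.nonzero(np.isnan(X))[1])
        raise ValueError(f"NaN features in columns {bad.tolist()}")
    if len(X) < 10:
        raise ValueError("need at least 10 samples to fit the forest")
    if mode == "importance":
        model = RandomForestRegressor(
            n_estimators=1000, max_depth=8, max_features=15, random_state=seed
        )
    elif mode == "prediction":
        model = RandomForestRegressor(n_estimators=20, random_state=seed)
    else:
        raise ValueError(f"unknown mode: {mode}")
    model.fit(X, y)
    return model, model.feature_importances_


def predict_efficiency(model: RandomForestRegressor, X: np.ndarray) -> np.ndarray:
    """Predicted normalized efficiencies, clipped to [0, 1]."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature count mismatch: model expects {model.n_features_in_}, got {X.shape[1]}"
        )
    return np.clip(model.predict(X), 0.0, 1.0)
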
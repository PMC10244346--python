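"""Keypoint-descriptor features: 448-D summaries, codebooks, bag-of-keypoints.

Three descriptor families are computed per image: SIFT (128-D float), a 64-D
binary descriptor family (BRIEF with 64 bits on Harris corner keypoints,
filling the 64-D slot conventionally occupied by the patent-encumbered SURF;
the substitution is recorded in the output metadata), and ORB (256-bit
binary descriptors packed to 32 bytes, the standard 32-D byte layout). The
per-image summary is the concatenation, family-major, of the per-dimension
mean and then standard deviation of all keypoint descriptors:
(128 + 64 + 32) x 2 = 448 values.

Bag-of-keypoints profiles quantize descriptors against a k-means codebook
(k = 256 for SIFT, k = 64 for ORB in the colony profile) and count the
keypoints assigned to each cluster.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.feature import BRIEF, ORB, SIFT, corner_harris, corner_peaks
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from pscml.well_io import WellImage

logger = logging.getLogger(__name__)

FAMILIES = ("sift", "brief64", "orb")
FAMILY_DIMS = {"sift": 128, "brief64": 64, "orb": 32}

#: Detector hyperparameters, fixed in one place. SIFT runs without the 2x
#: initial upsampling and with a lowered DoG threshold (CPU-budget choice
#: that roughly preserves keypoint counts on well-contrast colony texture).
SIFT_PARAMS = {"upsampling": 1, "c_dog": 0.02}
ORB_PARAMS = {"n_keypoints": 200, "n_scales": 3}
SUMMARY_DIM = 2 * sum(FAMILY_DIMS.values())  # 448


def _as_pixels(img: WellImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, WellImage) else np.asarray(img, dtype=float)


def extract_descriptors(img: WellImage | np.ndarray, family: str) -> np.ndarray:
    """Keypoint descriptors of one family; shape (n_keypoints, dim).

    Detector hyperparameters come from the module-level config block
    (SIFT_PARAMS, ORB_PARAMS); an image with no detectable keypoints yields
    an empty array.
    """
    px = _as_pixels(img)
    dim = FAMILY_DIMS[family]
    try:
        if family == "sift":
            det = SIFT(**SIFT_PARAMS)
            det.detect_and_extract(px)
            desc = det.descriptors.astype(np.float64)
        elif family == "orb":
            det = ORB(**ORB_PARAMS)
            det.detect_and_extract(px)
            # 256 binary values -> 32 bytes, the conventional ORB byte layout
            desc = np.packbits(det.descriptors.astype(np.uint8), axis=1).astype(np.float64)
        elif family == "brief64":
            keypoints = corner_peaks(corner_harris(px), min_distance=5, threshold_rel=0.01)
            extractor = BRIEF(descriptor_size=64, patch_size=25, rng=0)
            extractor.extract(px, keypoints)
            desc = extractor.descriptors.astype(np.float64)
        else:
            raise ValueError(f"unknown descriptor family: {family}")
    except (RuntimeError, IndexError, ValueError) as exc:
        # skimage detectors raise when an image has no usable structure
        logger.debug("descriptor extraction failed (%s): %s", family, exc)
        desc = np.empty((0, dim))
    if desc.size == 0:
        desc = np.empty((0, dim))
    return desc


@dataclass(frozen=True)
class DescriptorSummary:
    """448-D mean/std summary over the three descriptor families."""

    vector: np.ndarray
    n_keypoints: dict[str, int] = field(default_factory=dict)
    families: tuple[str, ...] = FAMILIES
    notes: str = "64-D family: BRIEF-64 on Harris corners (SURF unavailable)"

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=float))
        if self.vector.shape != (SUMMARY_DIM,):
            raise ValueError(f"descriptor summary must have length {SUMMARY_DIM}")


def descriptor_summary(img: WellImage | np.ndarray) -> DescriptorSummary:
    """Per-dimension mean then population std of all keypoint descriptors.

    Ordered family-major (SIFT means, SIFT stds, 64-D means, 64-D stds, ORB
    means, ORB stds). Images with no keypoints in a family contribute zeros
    for that family (with a warning).
    """
    parts: list[np.ndarray] = []
    counts: dict[str, int] = {}
    for family in FAMILIES:
        desc = extract_descriptors(img, family)
        counts[family] = len(desc)
        dim = FAMILY_DIMS[family]
        if len(desc) == 0:
            logger.warning("no %s keypoints found; summary block set to zero", family)
            parts.append(np.zeros(2 * dim))
        else:
            parts.append(np.concatenate([desc.mean(axis=0), desc.std(axis=0)]))
    return DescriptorSummary(vector=np.concatenate(parts), n_keypoints=counts)


# ---------------------------------------------------------------------------
# bag-of-keypoints codebooks


@dataclass
class Codebook:
    """k-means codebook over one descriptor family's keypoint space."""

    k: int
    centers: np.ndarray
    family: str
    seed: int
    fit_image_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.shape[0] != self.k:
            raise ValueError("center count must equal k")
        if not np.isfinite(self.centers).all():
            raise ValueError("codebook centers must be finite")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "k": self.k,
                    "family": self.family,
                    "seed": self.seed,
                    "fit_image_ids": list(self.fit_image_ids),
                    "centers": self.centers.tolist(),
                }
            )
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        d = json.loads(Path(path).read_text())
        return cls(
            k=d["k"],
            centers=np.asarray(d["centers"]),
            family=d["family"],
            seed=d["seed"],
            fit_image_ids=tuple(d["fit_image_ids"]),
        )


def fit_codebook(
    images: list[WellImage | np.ndarray],
    family: str,
    k: int,
    seed: int,
    image_ids: tuple[str, ...] = (),
) -> Codebook:
    """Fit a k-means codebook on all keypoint descriptors of a pool of images.

    The pool must be disjoint from any downstream train/test set; record its
    ids in ``image_ids`` so the disjointness can be enforced by callers.
    """
    pools = [extract_descriptors(img, family) for img in images]
    descriptors = np.vstack([p for p in pools if len(p)]) if any(len(p) for p in pools) else np.empty((0, FAMILY_DIMS[family]))
    if len(descriptors) < k:
        raise ValueError(
            f"need at least k={k} pooled keypoints to fit a codebook, got {len(descriptors)}"
        )
    km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    km.fit(descriptors)
    return Codebook(k=k, centers=km.cluster_centers_, family=family, seed=seed, fit_image_ids=image_ids)


def bag_of_keypoints(img: WellImage | np.ndarray, codebook: Codebook) -> np.ndarray:
    """Histogram of the image's keypoints over the codebook clusters.

    Each descriptor is assigned to its nearest center (Euclidean); the
    returned length-k count vector sums to the number of keypoints detected.
    """
    desc = extract_descriptors(img, codebook.family)
    counts = np.zeros(codebook.k, dtype=np.int64)
    if len(desc) == 0:
        return counts
    d2 = ((desc[:, None, :] - codebook.centers[None, :, :]) ** 2).sum(axis=2)
    assignment = d2.argmin(axis=1)
    np.add.at(counts, assignment, 1)
    return counts


# ---------------------------------------------------------------------------
# 2-D projections for trajectory visualization


def project_lda(
    X: np.ndarray, y: np.ndarray, shrinkage: float = 0.0
) -> tuple[np.ndarray, LinearDiscriminantAnalysis]:
    """First two linear discriminants separating dose classes.

    With shrinkage 0 the standard solver is used; a singular within-class
    scatter raises with a hint to use shrinkage > 0 (e.g. 0.1 as used for the
    21-D stream features).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("LDA needs at least two classes")
    lda = LinearDiscriminantAnalysis(
        solver="eigen", shrinkage=shrinkage if shrinkage > 0 else None, n_components=min(2, len(np.unique(y)) - 1)
    )
    try:
        Z = lda.fit_transform(X, y)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "within-class scatter is singular; retry with shrinkage > 0"
        ) from exc
    return Z, lda


def project_pca(X: np.ndarray) -> tuple[np.ndarray, PCA]:
    """First two principal components (for sample-distribution plots)."""
    pca = PCA(n_components=2)
    Z = pca.fit_transform(np.asarray(X, dtype=float))
    return Z, pca
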
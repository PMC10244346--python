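"""Handcrafted 21-D representation of a 0-12 h bright-field image stream.

Seven features describe how PSC colonies respond to CHIR within the first
twelve hours: a differential box-counting fractal dimension, local-entropy
statistics and colony-region statistics (area, circumference, their ratio,
brightness) per frame (Type-I), and a dense-optical-flow magnitude per
consecutive frame pair (Type-II). Sequences are normalized by their first
value where size-like, frames are pooled into pre/mid/post phases, and the
phase means are concatenated into a 21-vector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters.rank import entropy as rank_entropy
from skimage.measure import find_contours
from skimage.morphology import disk
from skimage.registration import optical_flow_ilk

from pscml.well_io import ImageStream, WellImage

logger = logging.getLogger(__name__)

#: Canonical feature order of the 21-vector: 7 features x {pre, mid, post}.
FEATURE_NAMES_7 = (
    "FractalDimension",
    "LocalEntropy",
    "Area",
    "Circumference",
    "ACRatio",
    "CellBrightness",
    "OpticalFlow",
)
PHASES = ("pre", "mid", "post")
STREAM_FEATURE_NAMES = tuple(f"{f}_{p}" for f in FEATURE_NAMES_7 for p in PHASES)

#: Frame indices (0-based) pooled per phase: Type-I features use the ten
#: frames T1..T10; Type-II (flow) uses the nine consecutive pairs.
TYPE1_PHASES = {"pre": (0, 1, 2), "mid": (3, 4, 5, 6), "post": (7, 8, 9)}
TYPE2_PHASES = {"pre": (0, 1, 2), "mid": (3, 4, 5), "post": (6, 7, 8)}

#: Features whose sequences are divided by their first value before pooling.
NORMALIZED_FEATURES = ("Area", "Circumference", "ACRatio", "OpticalFlow")
_NORM_EPS = 1e-6

#: Box-width schedule of the differential box counter: 2*k^i for i = 0..15
#: with k = 243**(1/15), i.e. geometric from 2 to 486.
DBC_N_SCALES = 16
DBC_K = 243.0 ** (1.0 / 15.0)
DBC_BOX_WIDTHS = tuple(2.0 * DBC_K**i for i in range(DBC_N_SCALES))
DBC_GRAY_LEVELS = 256


@dataclass(frozen=True)
class StreamFeatures:
    """Named 21-D feature vector of one image stream."""

    vector: np.ndarray
    names: tuple[str, ...] = STREAM_FEATURE_NAMES
    normalization_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=float))
        if self.vector.shape != (21,):
            raise ValueError("stream feature vector must have length 21")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.vector))


# ---------------------------------------------------------------------------
# cell-region segmentation by local entropy


def local_entropy_map(img: WellImage | np.ndarray, radius: int = 10) -> np.ndarray:
    """Per-pixel Shannon entropy (bits) of 8-bit intensities in a disc."""
    px = img.pixels if isinstance(img, WellImage) else np.asarray(img, dtype=float)
    quantized = np.round(np.clip(px, 0, 1) * 255).astype(np.uint8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank filters warn about bit depth
        ent = rank_entropy(quantized, disk(radius))
    return ent.astype(np.float64)


def cell_region_mask(
    img: WellImage | np.ndarray, radius: int = 10, entropy_threshold: float = 3.0
) -> np.ndarray:
    """Binary mask of cell-covered pixels: local entropy >= threshold (bits).

    Colony interiors are textured (high entropy) while the cell-free well
    bottom is nearly flat, so an entropy cut separates them.
    """
    return local_entropy_map(img, radius=radius) >= entropy_threshold


# ---------------------------------------------------------------------------
# differential box-counting fractal dimension


def _dbc_box_counts(gray: np.ndarray, r: float) -> tuple[int, float]:
    """Box count and realized box width for one nominal width r.

    The grid uses ``n = round(side/r)`` cells per axis, so the realized box
    width ``side/n`` (returned for the regression) differs slightly from the
    nominal schedule value; regressing on the realized width removes the
    quantization bias that nominal widths near the image side would cause.
    """
    side = max(gray.shape)
    n_r = max(1, round(gray.shape[0] / r))
    n_c = max(1, round(gray.shape[1] / r))
    r_eff = side / max(n_r, n_c)
    h = r_eff * DBC_GRAY_LEVELS / side  # intensity column height at this scale
    rows = np.minimum((np.arange(gray.shape[0]) * n_r) // gray.shape[0], n_r - 1)
    cols = np.minimum((np.arange(gray.shape[1]) * n_c) // gray.shape[1], n_c - 1)
    cell = rows[:, None] * n_c + cols[None, :]
    flat = cell.ravel()
    g = gray.ravel().astype(np.float64)
    n_cells = n_r * n_c
    gmax = np.full(n_cells, -np.inf)
    gmin = np.full(n_cells, np.inf)
    np.maximum.at(gmax, flat, g)
    np.minimum.at(gmin, flat, g)
    boxes = np.ceil(gmax / h) - np.ceil(gmin / h) + 1
    return int(boxes.sum()), r_eff


def dbc_box_widths(side: int) -> tuple[float, ...]:
    """16-value geometric box-width ladder from 2 to min(side, 486).

    Images at least 486 px wide use the canonical schedule ``2 * k**i``
    with ``k = 243**(1/15)``; smaller images use the same 16-step geometric
    construction ending at the image side, so the estimator stays defined
    at desk image sizes.
    """
    top = min(side, 486)
    if top < 4:
        raise ValueError("image too small for box counting")
    k = (top / 2.0) ** (1.0 / (DBC_N_SCALES - 1))
    return tuple(2.0 * k**i for i in range(DBC_N_SCALES))


def fractal_dimension(img: WellImage | np.ndarray) -> float:
    """Differential box-counting fractal dimension of a grayscale image.

    The image is treated as an intensity surface over the plane. For each
    box width r in the 16-value geometric schedule ``2 .. 486``, the plane is
    partitioned into r x r cells and the number of intensity boxes of height
    ``h = r * 256 / side`` needed to span each cell's min..max intensity is
    summed into N(r). The dimension is the negated slope of the least-squares
    fit of log N(r) against log r, clipped to the admissible surface range
    [2, 3] (with a warning when numerical error pushes it outside).
    """
    px = img.pixels if isinstance(img, WellImage) else np.asarray(img, dtype=float)
    side = max(px.shape)
    widths_schedule = dbc_box_widths(side)
    gray = np.round(np.clip(px, 0, 1) * (DBC_GRAY_LEVELS - 1))
    results = [_dbc_box_counts(gray, r) for r in widths_schedule]
    counts = [c for c, _ in results]
    widths = [w for _, w in results]
    slope = np.polyfit(np.log(widths), np.log(counts), 1)[0]
    fd = -float(slope)
    if not (2.0 <= fd <= 3.0):
        logger.warning("fractal dimension %.4f outside [2, 3]; clipping", fd)
        fd = float(np.clip(fd, 2.0, 3.0))
    return fd


# ---------------------------------------------------------------------------
# colony-region statistics


def mask_contour_length(mask: np.ndarray) -> float:
    """Total polygonal arc length of all outer contours of a binary mask."""
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        total += float(np.linalg.norm(np.diff(contour, axis=0), axis=1).sum())
    return total


def colony_stats(
    img: WellImage | np.ndarray, mask: np.ndarray
) -> tuple[float, float, float, float]:
    """(Area, Circumference, ACRatio, CellBrightness) of the cell regions.

    Area is the masked-pixel fraction; Circumference the total contour
    length divided by the image side; ACRatio their quotient (reflecting how
    much of the colony sits at its periphery); CellBrightness the mean
    intensity inside the mask. An empty mask yields four zeros with a warning.
    """
    px = img.pixels if isinstance(img, WellImage) else np.asarray(img, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != px.shape:
        raise ValueError("mask and image shapes differ")
    if not mask.any():
        logger.warning("empty cell mask; colony statistics set to 0")
        return 0.0, 0.0, 0.0, 0.0
    area = float(mask.mean())
    side = float(max(px.shape))
    circumference = mask_contour_length(mask) / side
    ac_ratio = area / circumference if circumference > 0 else 0.0
    brightness = float(px[mask].mean())
    return area, circumference, ac_ratio, brightness


# ---------------------------------------------------------------------------
# dense optical flow


def optical_flow_feature(
    prev: WellImage | np.ndarray,
    next_: WellImage | np.ndarray,
    window: int = 16,
    min_magnitude: float = 4.0,
) -> float:
    """Mean dense-flow magnitude between consecutive frames, in pixels.

    A dense optical-flow field is estimated with an iterative Lucas-Kanade
    solver whose integration window approximates ``window`` pixels; vectors
    with magnitude <= ``min_magnitude`` are discarded as noise and the mean
    magnitude of the survivors is returned (0 when none survive). The value
    tracks the contraction velocity of colony boundaries.
    """
    p = prev.pixels if isinstance(prev, WellImage) else np.asarray(prev, dtype=float)
    n = next_.pixels if isinstance(next_, WellImage) else np.asarray(next_, dtype=float)
    if p.shape != n.shape:
        raise ValueError("frames must have the same shape")
    radius = max(1, window // 2)
    v, u = optical_flow_ilk(
        p.astype(np.float32), n.astype(np.float32), radius=radius, num_warp=3
    )
    mag = np.hypot(u, v)
    survivors = mag[mag > min_magnitude]
    if survivors.size == 0:
        return 0.0
    return float(survivors.mean())


# ---------------------------------------------------------------------------
# the 21-D stream feature vector


def stream_feature_vector(
    stream: ImageStream,
    entropy_radius: int = 10,
    entropy_threshold: float = 3.0,
    flow_window: int = 16,
    flow_min_magnitude: float = 4.0,
) -> StreamFeatures:
    """Compute the 21-D feature vector of a 10-frame image stream.

    Type-I features are computed per frame; optical flow per consecutive
    pair. Area, Circumference, ACRatio and OpticalFlow sequences are divided
    by their first value (sequences whose first value is below 1e-6 are left
    unnormalized and flagged). Frames are pooled into pre/mid/post phases by
    arithmetic mean, giving 7 x 3 = 21 values in a stable name order.
    """
    frames = [f.pixels for f in stream.frames]
    n = len(frames)
    seqs: dict[str, np.ndarray] = {name: np.zeros(n) for name in FEATURE_NAMES_7 if name != "OpticalFlow"}
    for t, px in enumerate(frames):
        ent = local_entropy_map(px, radius=entropy_radius)
        mask = ent >= entropy_threshold
        seqs["FractalDimension"][t] = fractal_dimension(px)
        seqs["LocalEntropy"][t] = float(ent[mask].mean()) if mask.any() else 0.0
        area, circ, ac, bright = colony_stats(px, mask)
        seqs["Area"][t] = area
        seqs["Circumference"][t] = circ
        seqs["ACRatio"][t] = ac
        seqs["CellBrightness"][t] = bright
    seqs["OpticalFlow"] = np.array(
        [
            optical_flow_feature(frames[t], frames[t + 1], window=flow_window, min_magnitude=flow_min_magnitude)
            for t in range(n - 1)
        ]
    )

    flags: list[str] = []
    for name in NORMALIZED_FEATURES:
        first = seqs[name][0]
        if abs(first) < _NORM_EPS:
            flags.append(name)
            logger.warning("first value of %s below eps; sequence left unnormalized", name)
        else:
            seqs[name] = seqs[name] / first

    vector = np.empty(21)
    for i, name in enumerate(FEATURE_NAMES_7):
        phase_map = TYPE2_PHASES if name == "OpticalFlow" else TYPE1_PHASES
        for j, phase in enumerate(PHASES):
            vector[i * 3 + j] = float(np.mean(seqs[name][list(phase_map[phase])]))
    return StreamFeatures(vector=vector, normalization_flags=tuple(flags))
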
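"""Image, mask and table I/O, patch tiling, reconstruction, acquisition plans.

Intensity convention: every in-memory image is a float array in [0, 1];
8/16-bit integer scales appear only at file boundaries (and at the 0-255
class-activation-map normalization step, which is its own documented scale).
Coordinates are 0-based with half-open extents ``[r, r + patch)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

logger = logging.getLogger(__name__)

Channel = Literal["brightfield", "cTnT", "SIX2", "SOX17"]

#: 8-bit palette for fate-region masks: black = fails to commit,
#: light gray = likely commits, dark gray = commits, white = ground-truth
#: positive after recoloring.
MASK_BLACK = 0
MASK_LIGHT_GRAY = 128
MASK_DARK_GRAY = 192
MASK_WHITE = 255
MASK_PALETTE = (MASK_BLACK, MASK_LIGHT_GRAY, MASK_DARK_GRAY, MASK_WHITE)


@dataclass
class WellImage:
    """One grayscale whole-well image with metadata.

    ``pixels`` is a 2-D float array with intensities in [0, 1].
    """

    pixels: np.ndarray
    well_id: str = ""
    channel: str = "brightfield"
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"WellImage requires a 2-D array, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("WellImage requires a non-empty array")
        self.pixels = np.clip(px, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "WellImage":
        return replace(self, pixels=pixels)


@dataclass
class RegionMask:
    """Pixel labels for fate regions.

    Three-level annotation masks use the fixed palette
    {black, light_gray, dark_gray}; binary prediction masks use {0, 255}
    (or boolean arrays, normalized here to {0, 255}).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.dtype == bool:
            lab = np.where(lab, MASK_WHITE, MASK_BLACK).astype(np.uint8)
        lab = lab.astype(np.uint8)
        bad = set(np.unique(lab)) - set(MASK_PALETTE)
        if bad:
            raise ValueError(f"mask contains codes outside the palette: {sorted(bad)}")
        self.labels = lab

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def binary(self, positive_codes: Sequence[int] = (MASK_DARK_GRAY, MASK_WHITE)) -> np.ndarray:
        return np.isin(self.labels, positive_codes)


@dataclass
class ImageStream:
    """Ordered frames T1..T10 of one well over 0-12 h plus dose metadata."""

    frames: list[WellImage]
    timestamps_h: np.ndarray = field(default=None)  # type: ignore[assignment]
    chir_um: float = float("nan")
    chir_h: float = float("nan")
    well_id: str = ""

    N_FRAMES = 10

    def __post_init__(self) -> None:
        if len(self.frames) != self.N_FRAMES:
            raise ValueError(f"an image stream has exactly {self.N_FRAMES} frames, got {len(self.frames)}")
        if self.timestamps_h is None:
            self.timestamps_h = np.linspace(0.0, 12.0, self.N_FRAMES)
        self.timestamps_h = np.asarray(self.timestamps_h, dtype=float)
        if len(self.timestamps_h) != self.N_FRAMES:
            raise ValueError("timestamps must match the frame count")
        diffs = np.diff(self.timestamps_h)
        if not np.allclose(diffs, diffs[0]):
            raise ValueError("frames must be uniformly spaced in time")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class WellRecord:
    """Per-well tabular record: identifiers, CHIR dose, efficiency, class label."""

    well_id: str
    line: str
    batch: str
    chir_um: float
    chir_h: float
    efficiency: float | None = None
    dose_class: str | None = None

    def __post_init__(self) -> None:
        if self.chir_um <= 0:
            raise ValueError("CHIR concentration must be positive")
        if self.efficiency is not None and not (0.0 <= self.efficiency <= 1.0):
            raise ValueError("efficiency must lie in [0, 1]")


RECORD_COLUMNS = ["well_id", "line", "batch", "chir_um", "chir_h", "efficiency_index"]


def records_to_frame(records: Iterable[WellRecord]) -> pd.DataFrame:
    rows = [
        {
            "well_id": r.well_id,
            "line": r.line,
            "batch": r.batch,
            "chir_um": r.chir_um,
            "chir_h": r.chir_h,
            "efficiency_index": r.efficiency,
            "dose_class": r.dose_class,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# image file I/O


def read_image(path: str | Path, channel: str = "brightfield") -> WellImage:
    """Read an 8/16-bit grayscale TIFF or PNG as a [0, 1] float image.

    RGB inputs are converted to luminance with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:  # pragma: no cover - passthrough context
        raise IOError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3:
        logger.warning("RGB image %s converted to luminance", path)
        arr = arr @ np.array([0.2126, 0.7152, 0.0722])[: arr.shape[2]]
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
    else:
        scale = 1.0
    pixels = np.asarray(arr, dtype=np.float64) / scale
    return WellImage(pixels=pixels, well_id=path.stem, channel=channel)


def write_image(img: WellImage, path: str | Path) -> Path:
    """Write a WellImage: 16-bit for TIFF, 8-bit for PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    px = np.clip(img.pixels, 0.0, 1.0)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, np.round(px * 65535).astype(np.uint16))
    else:
        Image.fromarray(np.round(px * 255).astype(np.uint8)).save(path)
    return path


def read_mask(path: str | Path) -> RegionMask:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return RegionMask(labels=arr)


def write_mask(mask: RegionMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask.labels).save(path)
    return path


# ---------------------------------------------------------------------------
# tiling


def patch_origins(side: int, patch: int, overlap: float) -> list[int]:
    """1-D origins for tiling a side of length ``side`` with given overlap.

    Stride is ``round(patch * (1 - overlap))``; the final patch is re-anchored
    flush with the far edge so coverage is complete without padding.
    """
    if patch > side:
        raise ValueError(f"patch size {patch} exceeds image side {side}")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must lie in [0, 1)")
    stride = max(1, round(patch * (1.0 - overlap)))
    origins = list(range(0, side - patch + 1, stride))
    if origins[-1] + patch < side:
        origins.append(side - patch)
    return origins


def crop_patches(
    img: WellImage | np.ndarray, patch: int, overlap: float
) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Tile an image into overlapping patches.

    Returns ``(patch_pixels, (row, col))`` pairs in row-major order with
    0-based half-open extents ``[r, r+patch) x [c, c+patch)``.
    """
    px = img.pixels if isinstance(img, WellImage) else np.asarray(img)
    rows = patch_origins(px.shape[0], patch, overlap)
    cols = patch_origins(px.shape[1], patch, overlap)
    return [
        (px[r : r + patch, c : c + patch], (r, c))
        for r in rows
        for c in cols
    ]


def reconstruct(
    values: Sequence[np.ndarray],
    origins: Sequence[tuple[int, int]],
    out_size: tuple[int, int],
    aggregator: Literal["mean", "max", "any_positive"] = "mean",
) -> np.ndarray:
    """Stitch per-patch value maps back into a whole-well array.

    Overlap pixels are combined by the named aggregator. Every output pixel
    must be covered by at least one patch.
    """
    if len(values) != len(origins):
        raise ValueError("values and origins must have equal length")
    out_shape = tuple(out_size)
    count = np.zeros(out_shape, dtype=np.int64)
    if aggregator == "mean":
        acc = np.zeros(out_shape, dtype=np.float64)
    elif aggregator == "max":
        acc = np.full(out_shape, -np.inf)
    elif aggregator == "any_positive":
        acc = np.zeros(out_shape, dtype=bool)
    else:
        raise ValueError(f"unknown aggregator: {aggregator}")

    for val, (r, c) in zip(values, origins):
        val = np.asarray(val)
        h, w = val.shape
        sl = (slice(r, r + h), slice(c, c + w))
        count[sl] += 1
        if aggregator == "mean":
            acc[sl] += val
        elif aggregator == "max":
            acc[sl] = np.maximum(acc[sl], val)
        else:
            acc[sl] |= val > 0

    if (count == 0).any():
        gaps = np.argwhere(count == 0)
        raise ValueError(
            f"reconstruction leaves {len(gaps)} uncovered pixels; first gap at {tuple(gaps[0])}"
        )
    if aggregator == "mean":
        return acc / count
    return acc


# ---------------------------------------------------------------------------
# acquisition plan


def acquisition_plan(wells: int, grid: int, z_stacks: int) -> tuple[int, pd.DataFrame]:
    """Total tile count and tile coordinate table for a plate scan.

    Each well is imaged as a ``grid x grid`` tile pattern at ``z_stacks``
    focal planes, so one round acquires ``grid**2 * z_stacks * wells`` tiles
    (a 96-well 5x5x3 plan gives 7200).
    """
    if wells < 1 or grid < 1 or z_stacks < 1:
        raise ValueError("wells, grid and z_stacks must all be >= 1")
    total = grid * grid * z_stacks * wells
    well_idx, z_idx, row_idx, col_idx = np.meshgrid(
        np.arange(wells), np.arange(z_stacks), np.arange(grid), np.arange(grid), indexing="ij"
    )
    table = pd.DataFrame(
        {
            "well": well_idx.ravel(),
            "z": z_idx.ravel(),
            "tile_row": row_idx.ravel(),
            "tile_col": col_idx.ravel(),
        }
    )
    return total, table


# ---------------------------------------------------------------------------
# resizing conventions


def resize_image(px: np.ndarray, out_side: int) -> np.ndarray:
    """Bilinear resize for intensity images."""
    from skimage.transform import resize

    return resize(px, (out_side, out_side), order=1, anti_aliasing=True, preserve_range=True)


def resize_mask(labels: np.ndarray, out_side: int) -> np.ndarray:
    """Nearest-neighbor resize for label masks (palette-preserving)."""
    from skimage.transform import resize

    return resize(labels, (out_side, out_side), order=0, anti_aliasing=False, preserve_range=True).astype(labels.dtype)
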
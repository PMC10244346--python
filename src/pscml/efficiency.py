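"""Differentiation-efficiency quantification from fluorescence images.

The Differentiation Efficiency Index of a fluorescence image I (intensities
in [0, 1]) is the mean over all pixels of the intensities strictly above a
threshold alpha::

    Index = (1 / n_pixels) * sum_{I_ij > alpha} I_ij

with alpha = 0.5 by default. ``positive_fraction`` — the fraction of pixels
above alpha — doubles as a pixel-area proxy for the "percentage of
reporter-positive cells" used when labeling dose classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pscml.well_io import WellImage

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.5


@dataclass(frozen=True)
class EfficiencyResult:
    index: float
    positive_fraction: float
    alpha: float


def efficiency_index(fluor: WellImage | np.ndarray, alpha: float = DEFAULT_ALPHA) -> EfficiencyResult:
    """Intensity-weighted efficiency index of one fluorescence image.

    Pixels contribute only if their intensity is strictly greater than
    ``alpha``; the sum is normalized by the total pixel count, so the index
    is monotone in every pixel intensity and non-increasing in ``alpha``.
    """
    px = fluor.pixels if isinstance(fluor, WellImage) else np.asarray(fluor, dtype=float)
    if px.size == 0:
        raise ValueError("cannot compute an efficiency index of an empty image")
    positive = px > alpha
    index = float(px[positive].sum() / px.size)
    return EfficiencyResult(
        index=index,
        positive_fraction=float(positive.mean()),
        alpha=float(alpha),
    )


def normalize_efficiencies(
    records: pd.DataFrame,
    group_by: str = "line",
    column: str = "efficiency_index",
    out_column: str = "efficiency_norm",
) -> pd.DataFrame:
    """Normalize each well's efficiency by the maximum within its group.

    Differentiation potential differs between cell lines even under optimal
    induction, so efficiencies are expressed relative to the best well of the
    same line (values in [0, 1]; multiply by 100 for a percentage). Groups
    whose maximum is zero are set to 0 with a warning.
    """
    out = records.copy()
    normed = np.empty(len(out), dtype=float)
    for _, idx in out.groupby(group_by, sort=False).groups.items():
        vals = out.loc[idx, column].to_numpy(dtype=float)
        gmax = np.nanmax(vals) if len(vals) else 0.0
        if gmax <= 0:
            logger.warning("group with all-zero efficiencies normalized to 0")
            normed[out.index.get_indexer(idx)] = 0.0
        else:
            normed[out.index.get_indexer(idx)] = vals / gmax
    out[out_column] = normed
    return out
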
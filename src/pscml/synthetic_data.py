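"""Synthetic wells, image streams, masks and batch tables.

The generator emulates the statistical structure the analysis models assume,
so every module is testable without microscope data:

* multi-colony wells — ellipses with smoothed random boundary perturbation,
  band-limited noise texture inside, a darker domed base, and an illumination
  gradient plus sensor noise outside;
* a latent dose-response — differentiation propensity is a Gaussian bump in
  log-concentration centered on a line-specific optimum, so the
  fate-committed ("dark gray") area fraction is unimodal in the dose and
  maximal at the optimum;
* fated regions carry higher-variance texture than uncommitted colony area
  (what keypoint detectors and entropy filters respond to), and paired
  fluorescence is bright only inside fated regions, with noise added to the
  fluorescence rather than to the latent curve;
* 0-12 h streams — colonies contract radially and brighten at a rate that
  increases with the CHIR dose, with a fixed background so that all apparent
  motion is colony motion.

All randomness flows through one seeded generator per artifact; identical
plan + seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from pscml.efficiency import efficiency_index
from pscml.well_io import (
    MASK_BLACK,
    MASK_DARK_GRAY,
    MASK_LIGHT_GRAY,
    ImageStream,
    RegionMask,
    WellImage,
    WellRecord,
    records_to_frame,
    write_image,
    write_mask,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticPlan:
    """Study-condition parameters of a synthetic differentiation batch."""

    n_wells: int = 60
    cell_lines: tuple[str, ...] = ("L1",)
    concentrations: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)
    durations: tuple[float, ...] = (24.0,)
    optimal_center: Mapping[str, float] = field(default_factory=lambda: {"L1": 6.0})
    image_size: int = 256
    colonies_per_well: tuple[int, int] = (5, 8)
    noise_sd: float = 0.004
    seed: int = 0
    #: fate-committed area fraction of the whole well at the optimal dose
    max_dark_fraction: float = 0.25
    #: width (in log-concentration) of the dose-response bump
    log_sigma: float = 0.45
    #: exponent coupling duration to the effective optimum (longer exposure
    #: shifts the optimal concentration down, as titrations show)
    duration_exponent: float = 0.25
    #: standard deviation of colony interior texture (intensity units)
    texture_contrast: float = 0.10
    #: texture-s.d. ratio of fated over unfated colony regions
    fated_texture_margin: float = 2.0
    #: total 0-12 h radial contraction per uM of CHIR (fraction of radius)
    contraction_per_um: float = 0.035
    #: brightness gain of colonies over 0-12 h, scaled by the contraction
    brightening: float = 0.35

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if self.image_size < 256:
            raise ValueError("image_size must be >= 256")
        if self.n_wells < 0:
            raise ValueError("n_wells must be >= 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        for line in self.cell_lines:
            if line not in self.optimal_center:
                raise ValueError(f"no optimal_center given for line {line!r}")

    def latent_efficiency(self, dose: float, line: str, duration: float | None = None) -> float:
        """Gaussian-in-log-dose differentiation propensity in [0, 1]."""
        center = float(self.optimal_center[line])
        if duration is not None and len(self.durations) and duration != self.durations[0]:
            center = center * (self.durations[0] / duration) ** self.duration_exponent
        z = (np.log(dose) - np.log(center)) / self.log_sigma
        return float(np.exp(-0.5 * z * z))


# ---------------------------------------------------------------------------
# colony geometry


@dataclass(frozen=True)
class _Colony:
    center: tuple[float, float]
    radius: float
    aspect: float
    theta: float
    harmonics: np.ndarray  # (m, amplitude, phase) rows

    def rho(self, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
        """Normalized radial coordinate: <= 1 inside the colony."""
        cy, cx = self.center
        dy, dx = yy - cy, xx - cx
        ct, st = np.cos(self.theta), np.sin(self.theta)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        r = np.hypot(u / self.aspect, v)
        ang = np.arctan2(v, u / self.aspect)
        boundary = np.ones_like(ang)
        for m, amp, phase in self.harmonics:
            boundary = boundary + amp * np.cos(m * ang + phase)
        return r / (self.radius * np.maximum(boundary, 0.5))


def _sample_colonies(plan: SyntheticPlan, rng: np.random.Generator) -> list[_Colony]:
    n = int(rng.integers(plan.colonies_per_well[0], plan.colonies_per_well[1] + 1))
    size = plan.image_size
    colonies = []
    for _ in range(n):
        radius = rng.uniform(0.15, 0.22) * size
        center = tuple(rng.uniform(radius, size - radius, size=2))
        harmonics = np.column_stack(
            [
                np.arange(2, 6),
                rng.normal(0.0, 0.04, size=4),
                rng.uniform(0, 2 * np.pi, size=4),
            ]
        )
        colonies.append(
            _Colony(
                center=center,
                radius=radius,
                aspect=rng.uniform(0.7, 1.0),
                theta=rng.uniform(0, np.pi),
                harmonics=harmonics,
            )
        )
    return colonies


def _colony_bbox(colony: _Colony, size: int) -> tuple[slice, slice]:
    """Bounding box certainly containing the colony (rho <= 1 region)."""
    cy, cx = colony.center
    reach = colony.radius * 1.6  # boundary harmonics stay well under +60%
    r0 = max(0, int(cy - reach))
    r1 = min(size, int(cy + reach) + 1)
    c0 = max(0, int(cx - reach))
    c1 = min(size, int(cx + reach) + 1)
    return slice(r0, r1), slice(c0, c1)


def _rho_map(colonies: list[_Colony], size: int) -> np.ndarray:
    """Pixelwise minimum normalized radial coordinate over all colonies."""
    rho = np.full((size, size), np.inf)
    for colony in colonies:
        sl = _colony_bbox(colony, size)
        yy, xx = np.mgrid[sl[0], sl[1]].astype(np.float64)
        rho[sl] = np.minimum(rho[sl], colony.rho(yy, xx))
    return rho


def _bandlimited_noise(rng: np.random.Generator, size: int, sigma: float = 1.2) -> np.ndarray:
    """Zero-mean unit-variance smoothed noise field (colony texture)."""
    field_ = ndi.gaussian_filter(rng.standard_normal((size, size)), sigma)
    return field_ / field_.std()


# ---------------------------------------------------------------------------
# wells


def generate_well(
    plan: SyntheticPlan,
    dose: float,
    seed: int,
    line: str | None = None,
    duration: float | None = None,
) -> tuple[WellImage, WellImage, RegionMask]:
    """One synthetic well: bright-field image, fluorescence image, fate mask.

    The fate-committed area is the innermost colony pixels, sized so that its
    whole-well fraction equals ``max_dark_fraction`` times the latent
    dose-response at this dose (exact to one pixel). Fluorescence is bright
    only there; a thin transitional annulus is labeled light gray.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    line = line or plan.cell_lines[0]
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, int(seed) & 0x7FFFFFFF]))
    size = plan.image_size
    colonies = _sample_colonies(plan, rng)
    rho = _rho_map(colonies, size)
    colony_mask = rho <= 1.0

    e = plan.latent_efficiency(dose, line, duration)
    n_dark = int(round(plan.max_dark_fraction * e * size * size))
    n_colony = int(colony_mask.sum())
    if n_dark > n_colony:
        logger.warning("requested dark fraction exceeds colony coverage; capping")
        n_dark = n_colony

    labels = np.full((size, size), MASK_BLACK, dtype=np.uint8)
    dark = np.zeros((size, size), dtype=bool)
    if n_dark > 0:
        order = np.argsort(rho, axis=None, kind="stable")
        dark.ravel()[order[:n_dark]] = True
        rho_cut = float(rho.ravel()[order[n_dark - 1]])
        annulus = colony_mask & ~dark & (rho <= min(1.0, rho_cut * 1.12))
        labels[annulus] = MASK_LIGHT_GRAY
        labels[dark] = MASK_DARK_GRAY

    # bright-field: illumination gradient + sensor noise + textured colonies
    yy, xx = np.mgrid[0:size, 0:size] / size
    gx, gy = rng.uniform(-0.03, 0.03, size=2)
    bright = 0.55 + gx * (xx - 0.5) + gy * (yy - 0.5)
    bright = bright + rng.normal(0.0, plan.noise_sd, size=(size, size))
    tex = _bandlimited_noise(rng, size)
    bright[colony_mask] += plan.texture_contrast * tex[colony_mask] - 0.05
    bright[dark] += plan.texture_contrast * (plan.fated_texture_margin - 1.0) * tex[dark]

    # fluorescence: reporter signal confined to the fate-committed region
    fluor = np.abs(rng.normal(0.0, 0.01, size=(size, size)))
    if n_dark > 0:
        fluor[dark] = np.clip(0.60 + 0.30 * e + rng.normal(0.0, 0.05, size=n_dark), 0.51, 1.0)

    well_id = f"well-{seed}"
    return (
        WellImage(np.clip(bright, 0, 1), well_id=well_id, channel="brightfield"),
        WellImage(np.clip(fluor, 0, 1), well_id=well_id, channel="cTnT"),
        RegionMask(labels),
    )


# ---------------------------------------------------------------------------
# streams


def generate_stream(
    plan: SyntheticPlan,
    dose: float,
    seed: int,
    contraction_override: float | None = None,
) -> ImageStream:
    """A 10-frame 0-12 h stream of one well under CHIR at ``dose`` uM.

    Colonies contract radially toward their centers and brighten; both rates
    grow linearly with the dose (total radial contraction =
    ``contraction_per_um * dose``, capped at 0.6). The background field is
    frame-invariant, so colony contraction is the only apparent motion, and
    with a contraction coefficient of 0 all ten frames are identical.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, int(seed) & 0x7FFFFFFF, 1]))
    size = plan.image_size
    colonies = _sample_colonies(plan, rng)
    gamma = (
        float(contraction_override)
        if contraction_override is not None
        else min(0.6, plan.contraction_per_um * dose)
    )

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    gx, gy = rng.uniform(-0.03, 0.03, size=2)
    background = 0.55 + gx * (xx / size - 0.5) + gy * (yy / size - 0.5)
    background = background + rng.normal(0.0, plan.noise_sd, size=(size, size))
    texture = _bandlimited_noise(rng, size)

    rho0 = [c.rho(yy, xx) for c in colonies]
    n_frames = ImageStream.N_FRAMES
    frames = []
    for t in range(n_frames):
        scale = 1.0 - gamma * t / (n_frames - 1)
        delta = plan.brightening * gamma * t / (n_frames - 1)
        px = background.copy()
        claimed = np.full((size, size), np.inf)
        for colony, rho in zip(colonies, rho0):
            inside = (rho <= scale) & (rho < claimed)
            if not inside.any():
                continue
            claimed[inside] = rho[inside]
            cy, cx = colony.center
            src_y = cy + (yy[inside] - cy) / scale
            src_x = cx + (xx[inside] - cx) / scale
            tex_vals = ndi.map_coordinates(texture, [src_y, src_x], order=1, mode="reflect")
            px[inside] = (
                background[inside] - 0.05 + plan.texture_contrast * tex_vals + delta
            )
        frames.append(
            WellImage(np.clip(px, 0, 1), well_id=f"stream-{seed}-T{t + 1}", channel="brightfield")
        )
    return ImageStream(frames=frames, chir_um=dose, chir_h=plan.durations[0], well_id=f"stream-{seed}")


# ---------------------------------------------------------------------------
# batches


def generate_batch(
    plan: SyntheticPlan,
    batch_id: str = "B1",
    seed_offset: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, dict[str, object]]]:
    """A full batch: one record per well plus an image store.

    Wells cycle over cell lines x concentrations x durations. Each record's
    efficiency is the Differentiation Efficiency Index computed from the
    generated fluorescence image (so the table is consistent with the images
    by construction). With ``out_dir`` set, bright-field images are written
    as 16-bit TIFF, fluorescence as TIFF, masks as 8-bit PNG, and the table
    as CSV; otherwise the store holds the in-memory objects.
    """
    records: list[WellRecord] = []
    store: dict[str, dict[str, object]] = {}
    combos = [
        (line, conc, dur)
        for line in plan.cell_lines
        for dur in plan.durations
        for conc in plan.concentrations
    ]
    for i in range(plan.n_wells):
        line, conc, dur = combos[i % len(combos)]
        well_seed = seed_offset + i
        bright, fluor, mask = generate_well(plan, conc, well_seed, line=line, duration=dur)
        eff = efficiency_index(fluor).index
        well_id = f"{batch_id}-{i:04d}"
        records.append(
            WellRecord(
                well_id=well_id,
                line=line,
                batch=batch_id,
                chir_um=conc,
                chir_h=dur,
                efficiency=min(1.0, eff),
            )
        )
        store[well_id] = {"bright": bright, "fluor": fluor, "mask": mask, "seed": well_seed}
        if out_dir is not None:
            out = Path(out_dir)
            write_image(bright, out / f"{well_id}_bright.tiff")
            write_image(fluor, out / f"{well_id}_ctnt.tiff")
            write_mask(mask, out / f"{well_id}_mask.png")

    table = records_to_frame(records)
    if len(table):
        table["seed"] = [store[w]["seed"] for w in table["well_id"]]
    if out_dir is not None and len(table):
        table.to_csv(Path(out_dir) / f"{batch_id}_wells.csv", index=False)
    return table, store
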
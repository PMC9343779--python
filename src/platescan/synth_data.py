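"""Synthetic plate scans and growth kinetics for end-to-end testing.

Emulates the data a flatbed scanner produces when a black-covered microplate
is scanned from below: each well shows a bright refraction ring around a
central shadow, and the contrast of that pattern fades monotonically as the
culture gets more turbid. The kinetics side simulates modified-Gompertz OD620
trajectories with antibiotic dose effects (longer lag, lower plateau) that
saturate along a Hill curve in concentration.

The rendering is stylized, not a physical optics model: its single contract
is that ring-versus-center contrast decreases strictly with OD. The ring has
a smooth Gaussian radial profile, so pixel averaging resolves contrast well
below the 8-bit quantization step. Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .density_model import ClassificationLevels, default_levels, od_to_level, od_to_level_array
from .plate_imaging import (
    PLATE_COLS,
    PLATE_ROWS,
    PlateImage,
    PlateMask,
    WellImage,
    default_mask,
    flip_plate_image,
    save_mask,
    save_plate_image,
)
from .training_prep import ODGrid, save_od_grid

#: Chloramphenicol-style dose series used by the default sample-run layout (ug/L).
DEFAULT_DOSES = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0, 16000.0, 32000.0)


@dataclass(frozen=True)
class DoseEffect:
    """Saturating (Hill-shaped) antibiotic effect on lag and plateau.

    At concentration c the effect fraction is e(c) = c^k / (ec50^k + c^k);
    the lag extends by ``max_lag_extension_min * e`` and the OD plateau drops
    by ``od_max_suppression_fraction * e`` of its rise above the inoculum.
    """

    ec50_ugL: float = 2000.0
    hill_k: float = 2.0
    max_lag_extension_min: float = 600.0
    od_max_suppression_fraction: float = 0.9

    def effect(self, concentration: float) -> float:
        if concentration <= 0:
            return 0.0
        r = (concentration / self.ec50_ugL) ** self.hill_k
        return r / (1.0 + r)


@dataclass(frozen=True)
class KineticsParams:
    """Modified-Gompertz OD620 kinetics of one well.

    Defaults emulate an overnight E. coli culture diluted to a low inoculum:
    OD 0.01 start, plateau 1.0, maximum slope 0.005 OD/min, 120 min lag,
    additive OD read noise of 0.01.
    """

    od_start: float = 0.01
    od_max: float = 1.0
    mu_m: float = 0.005  # OD/min at steepest growth
    lam: float = 120.0  # lag, minutes
    noise_sd: float = 0.01
    dose_effect: DoseEffect = field(default_factory=DoseEffect)

    def __post_init__(self) -> None:
        if self.od_start >= self.od_max:
            raise ValueError("od_start must be below od_max")
        if self.lam < 0 or self.noise_sd < 0:
            raise ValueError("lam and noise_sd must be non-negative")


def simulate_od_trajectory(
    params: KineticsParams,
    concentration: float,
    times: Sequence[float],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """OD620 trajectory at the given minutes, with dose effect and read noise.

    Concentration 0 with zero noise reproduces the exact Gompertz trajectory
    with the nominal lag and plateau; at full suppression the trajectory stays
    at the inoculum density.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    e = params.dose_effect.effect(concentration)
    lam_eff = params.lam + params.dose_effect.max_lag_extension_min * e
    od_max_eff = params.od_start + (params.od_max - params.od_start) * (
        1.0 - params.dose_effect.od_max_suppression_fraction * e
    )
    A = od_max_eff - params.od_start
    if A <= 1e-9:
        od = np.full_like(t, params.od_start)
    else:
        od = params.od_start + A * np.exp(
            -np.exp(params.mu_m * math.e / A * (lam_eff - t) + 1.0)
        )
    if params.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        od = od + rng.normal(0.0, params.noise_sd, size=od.shape)
    return np.clip(od, 0.0, None)


# ---------------------------------------------------------------------------
# well rendering


@dataclass(frozen=True)
class WellRenderParams:
    """Geometry and radiometry of the stylized well rendering.

    Ring-versus-center contrast is ``base_ring_contrast * exp(-decay_rate *
    od)``: exactly ``base_ring_contrast`` for a blank well and strictly
    decreasing in OD. The interior also brightens mildly with turbidity
    (scattered light), a secondary monotone cue.
    """

    well_diameter_px: int = 31
    ring_radius_fraction: float = 0.75
    ring_width_fraction: float = 0.10  # Gaussian sigma of the ring profile, in radii
    base_ring_contrast: float = 140.0
    contrast_decay_rate: float = 2.5  # per OD unit
    pixel_noise_sd: float = 3.0
    background_gray: float = 30.0
    interior_gray: float = 110.0
    turbidity_brightening: float = 25.0

    def contrast_decay(self, od: float) -> float:
        return math.exp(-self.contrast_decay_rate * od)


def render_well(
    od: float,
    params: WellRenderParams = WellRenderParams(),
    seed: int | np.random.Generator = 0,
    label: str = "A1",
    slice_index: int = 0,
) -> WellImage:
    """Render one well raster at a given OD (deterministic per seed)."""
    return WellImage(
        label=label,
        pixels=_render_pixels(od, params, seed),
        slice_index=slice_index,
    )


def _render_pixels(
    od: float, params: WellRenderParams, seed: int | np.random.Generator
) -> np.ndarray:
    n = params.well_diameter_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c) / (n / 2.0)  # 0 at center, 1 at inscribed edge
    decay = params.contrast_decay(od)
    contrast = params.base_ring_contrast * decay
    interior = params.interior_gray + params.turbidity_brightening * (1.0 - decay)
    img = np.full((n, n), params.background_gray, dtype=np.float64)
    disk = r <= 1.0
    # smooth Gaussian ring over a central shadow; ring-center contrast == `contrast`
    ring_profile = np.exp(-0.5 * ((r - params.ring_radius_fraction) / params.ring_width_fraction) ** 2)
    shadow = 0.5 * contrast * (1.0 - ring_profile)
    img[disk] = interior + 0.5 * contrast * ring_profile[disk] - shadow[disk]
    if params.pixel_noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        img = img + rng.normal(0.0, params.pixel_noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# whole-run generation


def default_layout(doses: Sequence[float] = DEFAULT_DOSES) -> dict[str, tuple[str, float]]:
    """Sample-run plate layout: two antibiotics x 8 doses x 3 replicate rows.

    Rows A-C carry ``drugA`` (shallow, k=1) and D-F ``drugB`` (steep, k=4) in
    columns 1-8; columns 9-10 are drug-free growth controls, 11-12 sterile
    blanks. Rows G and H are extra growth controls and blanks.
    """
    layout: dict[str, tuple[str, float]] = {}
    for rows, drug in (("ABC", "drugA"), ("DEF", "drugB")):
        for r in rows:
            for ci, dose in enumerate(doses, start=1):
                layout[f"{r}{ci}"] = (drug, dose)
            layout[f"{r}9"] = (drug, 0.0)
            layout[f"{r}10"] = (drug, 0.0)
            layout[f"{r}11"] = ("blank", 0.0)
            layout[f"{r}12"] = ("blank", 0.0)
    for c in PLATE_COLS:
        layout[f"G{c}"] = ("", 0.0)
        layout[f"H{c}"] = ("blank", 0.0)
    return layout


@dataclass(frozen=True)
class SyntheticPlateSpec:
    """Everything needed to render a deterministic plate-image series."""

    mask: PlateMask = field(default_factory=default_mask)
    layout: Mapping[str, tuple[str, float]] = field(default_factory=default_layout)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    drug_effects: Mapping[str, DoseEffect] = field(
        default_factory=lambda: {
            "drugA": DoseEffect(hill_k=1.0),
            "drugB": DoseEffect(hill_k=4.0),
        }
    )
    render: WellRenderParams = field(default_factory=WellRenderParams)
    interval_minutes: float = 30.0
    n_timepoints: int = 93
    seed: int = 0

    def well_kinetics(self, label: str) -> tuple[KineticsParams, float]:
        """(kinetics, concentration) of one well; blanks never grow."""
        drug, conc = self.layout.get(label, ("", 0.0))
        kp = self.kinetics
        if drug == "blank":
            # sterile broth: stays at a residual background OD
            kp = replace(kp, od_start=0.005, od_max=0.0051, lam=0.0)
            return kp, 0.0
        if drug and drug in self.drug_effects:
            kp = replace(kp, dose_effect=self.drug_effects[drug])
        return kp, conc


@dataclass
class GeneratedRun:
    """Paths and ground truth written by :func:`generate_run`."""

    out_dir: Path
    image_paths: list[Path]
    mask_path: Path
    layout_path: Path
    od_truth_path: Path
    level_truth_path: Path
    od_truth: pd.DataFrame  # rows: timepoints, columns: wells
    level_truth: pd.DataFrame


def _well_seed(base_seed: int, what: int, index: int, timepoint: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((base_seed, what, index, timepoint)))


def generate_run(
    spec: SyntheticPlateSpec,
    out_dir: str | Path,
    levels: ClassificationLevels | None = None,
) -> GeneratedRun:
    """Render a full synthetic scan series plus layout and ground-truth tables.

    Writes ``frame_<i:03d>.png`` plate images (mirrored, as a scanner would
    deliver them, so the standard horizontal flip re-aligns them with the
    mask), the mask and layout CSVs, and per-timepoint ground-truth OD and
    level tables. Byte-identical for a fixed spec (lossless PNG).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    levels = levels or default_levels()
    times = np.arange(spec.n_timepoints, dtype=float) * spec.interval_minutes
    labels = spec.mask.labels

    od_cols: dict[str, np.ndarray] = {}
    for wi, label in enumerate(labels):
        kp, conc = spec.well_kinetics(label)
        rng = _well_seed(spec.seed, 1, wi)
        od_cols[label] = simulate_od_trajectory(kp, conc, times, seed=rng)
    od_truth = pd.DataFrame(od_cols, index=times)
    od_truth.index.name = "minutes"
    level_truth = od_truth.apply(lambda col: od_to_level_array(col.to_numpy(), levels))

    width, height = spec.mask.extent()
    width += 40
    height += 40
    image_paths: list[Path] = []
    for ti in range(spec.n_timepoints):
        canvas = np.full((height, width), spec.render.background_gray, dtype=np.float64)
        canvas = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
        for wi, region in enumerate(spec.mask.wells):
            rng = _well_seed(spec.seed, 2, wi, ti)
            od = float(od_truth.iloc[ti][region.label])
            rp = replace(
                spec.render,
                well_diameter_px=min(region.width, region.height),
            )
            px = _render_pixels(od, rp, rng)
            canvas[
                region.y : region.y + px.shape[0], region.x : region.x + px.shape[1]
            ] = px
        plate = PlateImage(pixels=canvas, timestamp=times[ti])
        mirrored = flip_plate_image(plate, "horizontal")  # scanner delivers mirrored frames
        path = out_dir / f"frame_{ti:03d}.png"
        save_plate_image(mirrored, path)
        image_paths.append(path)

    mask_path = save_mask(spec.mask, out_dir / "mask.csv")
    layout_path = out_dir / "layout.csv"
    pd.DataFrame(
        [(w, d, c) for w, (d, c) in sorted(spec.layout.items())],
        columns=["well", "antibiotic", "concentration_ugL"],
    ).to_csv(layout_path, index=False)
    od_truth_path = out_dir / "truth_od.csv"
    od_truth.to_csv(od_truth_path)
    level_truth_path = out_dir / "truth_levels.csv"
    level_truth.to_csv(level_truth_path)
    return GeneratedRun(
        out_dir=out_dir,
        image_paths=image_paths,
        mask_path=mask_path,
        layout_path=layout_path,
        od_truth_path=od_truth_path,
        level_truth_path=level_truth_path,
        od_truth=od_truth,
        level_truth=level_truth,
    )


# ---------------------------------------------------------------------------
# training-set generation


def level_od_grid(levels: ClassificationLevels, level: int, n: int, od_cap: float = 1.2) -> np.ndarray:
    """Evenly spaced ODs covering a level's [lower, upper) interval.

    Spans the closed lower edge up to just inside the open upper edge
    (within 1e-6 OD), so the classifier sees each class's extremes; the
    unbounded top level is capped at ``od_cap``.
    """
    lower, upper = levels.interval(level)
    upper = min(upper, od_cap)
    if n == 1:
        return np.array([lower])
    eps = min(1e-6, (upper - lower) / (10.0 * n))
    return np.linspace(lower, upper - eps, n)


def generate_training_set(
    levels: ClassificationLevels,
    n_per_level: int,
    render: WellRenderParams = WellRenderParams(),
    seed: int = 0,
    out_dir: str | Path = "training_set",
    od_cap: float = 1.2,
) -> dict[int, int]:
    """Write a level-sorted training tree plus companion OD spreadsheets.

    ``level_<k>/`` holds ``n_per_level`` rendered wells per level, named with
    their OD tag. Complete groups of 96 samples are additionally written as
    labelled OD-grid CSVs under ``grids/`` with matching raw well images under
    ``raw/plate_<p>/``, so the tag -> group workflow can be exercised against
    known truth. Returns per-level file counts.
    """
    out_dir = Path(out_dir)
    samples: list[tuple[int, float]] = []  # (level, od) in a stable plate-filling order
    counts: dict[int, int] = {}
    for level in range(1, levels.n_levels + 1):
        ods = level_od_grid(levels, level, n_per_level, od_cap)
        d = out_dir / f"level_{level}"
        d.mkdir(parents=True, exist_ok=True)
        for i, od in enumerate(ods):
            rng = _well_seed(seed, 3, level, i)
            px = _render_pixels(float(od), render, rng)
            Image.fromarray(px, mode="L").save(d / f"L{level}_{i:04d}_{od:.3f}.png")
            samples.append((level, float(od)))
        counts[level] = len(ods)

    # companion OD grids + raw wells, one plate per 96 consecutive samples
    labels96 = [f"{r}{c}" for r in PLATE_ROWS for c in PLATE_COLS]
    n_plates = len(samples) // 96
    if n_plates:
        (out_dir / "grids").mkdir(exist_ok=True)
    for p in range(n_plates):
        chunk = samples[p * 96 : (p + 1) * 96]
        grid = ODGrid(
            {lab: od for lab, (_, od) in zip(labels96, chunk)}, plate_id=f"plate_{p}"
        )
        save_od_grid(grid, out_dir / "grids" / f"plate_{p}_od.csv")
        raw = out_dir / "raw" / f"plate_{p}"
        raw.mkdir(parents=True, exist_ok=True)
        for lab, (lvl, od) in zip(labels96, chunk):
            rng = _well_seed(seed, 4, p * 96 + labels96.index(lab))
            px = _render_pixels(od, render, rng)
            Image.fromarray(px, mode="L").save(raw / f"{lab}.png")
    return counts
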
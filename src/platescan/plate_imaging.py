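"""Reading scanned microplate images and slicing them into labelled well images.

A scanned plate arrives as a single grayscale raster. An *image mask* — a CSV
table of pixel rectangles, one per well — maps that raster onto the 8x12 grid
of a 96-well plate. The processing chain applied to every frame of a run is
flip (scanner output is mirrored) -> crop into per-well slices -> classify.

Coordinates are 0-based and rectangles half-open: a region (x, y, w, h)
covers pixel columns [x, x+w) and rows [y, y+h). Color inputs are converted
to 8-bit grayscale with the ITU-R 601 luminance weighting
L = 0.299 R + 0.587 G + 0.114 B, identically at training and inference time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import MaskBoundsError, MaskFormatError

logger = logging.getLogger(__name__)

FlipAxis = Literal["horizontal", "vertical", "none"]

WELL_LABEL_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")

#: Row letters and column numbers of a standard 96-well plate, scanning order
#: (row-major: A1..A12, B1..B12, ..., H12).
PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = tuple(range(1, 13))
WELL_LABELS_96 = tuple(f"{r}{c}" for r in PLATE_ROWS for c in PLATE_COLS)


def well_sort_key(label: str) -> tuple[int, int]:
    """Row-major sort key for well labels (A1 < A2 < ... < A12 < B1 < ...)."""
    return (ord(label[0]) - ord("A"), int(label[1:]))


@dataclass(frozen=True)
class WellRegion:
    """One labelled pixel rectangle of the image mask (half-open)."""

    label: str
    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if not WELL_LABEL_RE.match(self.label):
            raise MaskFormatError(f"invalid well label {self.label!r}")
        if self.x < 0 or self.y < 0:
            raise MaskFormatError(f"negative origin for well {self.label}: ({self.x}, {self.y})")
        if self.width <= 0 or self.height <= 0:
            raise MaskFormatError(
                f"non-positive size for well {self.label}: {self.width}x{self.height}"
            )


@dataclass(frozen=True)
class PlateMask:
    """Pixel geometry mapping one scanned plate image to labelled well rectangles."""

    wells: tuple[WellRegion, ...]
    source_path: str = ""
    plate_rows: int = 8
    plate_cols: int = 12

    def __post_init__(self) -> None:
        labels = [w.label for w in self.wells]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise MaskFormatError(f"duplicate well labels in mask: {sorted(dupes)}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(w.label for w in self.wells)

    def extent(self) -> tuple[int, int]:
        """(width, height) of the smallest image that fits every rectangle."""
        return (
            max(w.x + w.width for w in self.wells),
            max(w.y + w.height for w in self.wells),
        )

    def mirrored(self, image_width: int) -> "PlateMask":
        """The mask seen through a horizontal flip of an image of given width."""
        mirrored = tuple(
            replace(w, x=image_width - w.x - w.width) for w in self.wells
        )
        return PlateMask(mirrored, self.source_path, self.plate_rows, self.plate_cols)


@dataclass(frozen=True)
class PlateImage:
    """One grayscale scan of a whole plate; timestamp in minutes from run start."""

    pixels: np.ndarray
    timestamp: float | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("plate image must be a 2-D grayscale raster")


@dataclass(frozen=True)
class WellImage:
    """A cropped single-well raster in scanning order."""

    label: str
    pixels: np.ndarray
    slice_index: int
    parent_timestamp: float | None = None


def load_mask(path: str | Path) -> PlateMask:
    """Load an image mask CSV (header ``label,x,y,width,height``).

    Rows are returned sorted row-major by well label regardless of file order;
    duplicate labels and negative geometry are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["label", "x", "y", "width", "height"]
    if list(df.columns[: len(expected)]) != expected:
        raise MaskFormatError(
            f"mask header must be {','.join(expected)}, got {','.join(map(str, df.columns))}"
        )
    if df["label"].isna().any():
        raise MaskFormatError("mask contains a row with a missing label")
    rows = []
    for rec in df.itertuples(index=False):
        try:
            rows.append(
                WellRegion(str(rec.label), int(rec.x), int(rec.y), int(rec.width), int(rec.height))
            )
        except (TypeError, ValueError) as exc:
            raise MaskFormatError(f"non-integer geometry for well {rec.label!r}") from exc
    rows.sort(key=lambda w: well_sort_key(w.label))
    return PlateMask(tuple(rows), source_path=str(path))


def default_mask(
    origin: tuple[int, int] = (40, 40),
    pitch: tuple[int, int] = (36, 36),
    well_size: tuple[int, int] = (31, 31),
    rows: int = 8,
    cols: int = 12,
) -> PlateMask:
    """Parametric 8x12 mask (origin, pitch and well size in pixels).

    The published mask coordinates are scanner-specific, so a regular grid is
    generated instead and can be written out with :func:`save_mask`.
    """
    wells = []
    for ri in range(rows):
        for ci in range(cols):
            label = f"{PLATE_ROWS[ri]}{ci + 1}"
            wells.append(
                WellRegion(
                    label,
                    origin[0] + ci * pitch[0],
                    origin[1] + ri * pitch[1],
                    well_size[0],
                    well_size[1],
                )
            )
    return PlateMask(tuple(wells), source_path="<default>")


def save_mask(mask: PlateMask, path: str | Path) -> Path:
    """Write a mask back to its CSV form."""
    path = Path(path)
    df = pd.DataFrame(
        [(w.label, w.x, w.y, w.width, w.height) for w in mask.wells],
        columns=["label", "x", "y", "width", "height"],
    )
    df.to_csv(path, index=False)
    return path


def load_plate_image(path: str | Path, timestamp: float | None = None) -> PlateImage:
    """Read a plate scan (PNG/TIFF lossless; JPEG accepted with a warning)."""
    path = Path(path)
    if path.suffix.lower() in (".jpg", ".jpeg"):
        logger.warning("reading lossy JPEG image %s; PNG or TIFF is recommended", path)
    with Image.open(path) as im:
        gray = im.convert("L")  # ITU-R 601 luminance
        pixels = np.asarray(gray, dtype=np.uint8)
    return PlateImage(pixels=pixels, timestamp=timestamp, source_path=str(path))


def save_plate_image(img: PlateImage, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(img.pixels, mode="L").save(path)
    return path


def flip_plate_image(img: PlateImage, axis: FlipAxis = "horizontal") -> PlateImage:
    """Mirror a plate image; applying the same flip twice is the identity."""
    if axis == "none":
        return img
    if axis == "horizontal":
        return replace(img, pixels=np.fliplr(img.pixels))
    if axis == "vertical":
        return replace(img, pixels=np.flipud(img.pixels))
    raise ValueError(f"unknown flip axis {axis!r}")


def slice_plate(img: PlateImage, mask: PlateMask) -> list[WellImage]:
    """Crop one :class:`WellImage` per mask entry, in scanning order."""
    h, w = img.pixels.shape
    out: list[WellImage] = []
    for idx, region in enumerate(mask.wells):
        if region.x + region.width > w or region.y + region.height > h:
            raise MaskBoundsError(region.label)
        crop = img.pixels[region.y : region.y + region.height, region.x : region.x + region.width]
        out.append(
            WellImage(
                label=region.label,
                pixels=crop.copy(),
                slice_index=idx,
                parent_timestamp=img.timestamp,
            )
        )
    return out


def flip_well_image(well: WellImage, axis: FlipAxis = "horizontal") -> WellImage:
    if axis == "none":
        return well
    flipped = np.fliplr(well.pixels) if axis == "horizontal" else np.flipud(well.pixels)
    return replace(well, pixels=flipped)


def save_well_images(
    wells: Sequence[WellImage],
    out_dir: str | Path,
    naming: Literal["by_order", "by_well", "by_od"] = "by_order",
    od_map: Mapping[str, float] | None = None,
) -> list[Path]:
    """Write well slices as PNG files.

    ``by_order``: files ``000.png..095.png`` named by slice index in one
    directory. ``by_well``: one subdirectory per well label; successive calls
    (e.g. one per timepoint) append sequentially numbered files. ``by_od``:
    files named ``<label>_<od:.3f>.png`` using ``od_map``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for wimg in wells:
        if naming == "by_order":
            target = out_dir / f"{wimg.slice_index:03d}.png"
        elif naming == "by_well":
            sub = out_dir / wimg.label
            sub.mkdir(exist_ok=True)
            n_existing = sum(1 for p in sub.iterdir() if p.suffix == ".png")
            target = sub / f"{n_existing:03d}.png"
        elif naming == "by_od":
            if od_map is None or wimg.label not in od_map:
                raise ValueError(f"by_od naming requires an OD value for well {wimg.label}")
            target = out_dir / f"{wimg.label}_{od_map[wimg.label]:.3f}.png"
        else:
            raise ValueError(f"unknown naming scheme {naming!r}")
        Image.fromarray(wimg.pixels, mode="L").save(target)
        written.append(target)
    return written


def load_well_image(path: str | Path, label: str | None = None, slice_index: int = 0) -> WellImage:
    """Read a single well image; label defaults to one parsed from the filename."""
    path = Path(path)
    if label is None:
        m = re.search(r"([A-H](?:1[0-2]|[1-9]))", path.stem)
        label = m.group(1) if m else "A1"
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("L"), dtype=np.uint8)
    return WellImage(label=label, pixels=pixels, slice_index=slice_index)
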
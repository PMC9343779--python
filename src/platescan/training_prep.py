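"""Assistive workflows for building and evaluating classification models.

Three jobs mirror the model-building workflow of the original tool: tag well
images with externally measured OD620 values, sort tagged images into
per-level folders ready for training, and test a trained model against
spectrophotometric ground truth. A fourth builds a validation set by
horizontally mirroring a level-sorted training tree.
"""

from __future__ import annotations

import logging
import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .density_model import ClassificationLevels, WellClassifier, classify_well, od_to_level
from .errors import EmptyEvaluationError, MatchError, SpreadsheetFormatError
from .plate_imaging import PLATE_COLS, PLATE_ROWS, WELL_LABELS_96, WellImage, flip_well_image, load_well_image
from PIL import Image

logger = logging.getLogger(__name__)

_OD_SUFFIX_RE = re.compile(r"_(\d+\.\d{3})$")


@dataclass(frozen=True)
class ODGrid:
    """An 8x12 plate of OD620 readings; missing wells are None, never zero."""

    values: Mapping[str, float | None]
    source_path: str = ""
    plate_id: str = "plate"

    def __post_init__(self) -> None:
        missing_labels = set(WELL_LABELS_96) - set(self.values)
        if missing_labels:
            raise SpreadsheetFormatError(f"grid lacks wells: {sorted(missing_labels)[:5]} ...")
        for label, v in self.values.items():
            if v is not None and (not np.isfinite(v) or v < 0):
                raise SpreadsheetFormatError(f"invalid OD {v!r} at well {label}")

    def get(self, label: str) -> float | None:
        return self.values[label]

    @property
    def n_present(self) -> int:
        return sum(v is not None for v in self.values.values())


def _grid_from_frame(df: pd.DataFrame, path: str, plate_id: str) -> ODGrid:
    """Extract the 8x12 block from a raw spreadsheet frame.

    Accepts either a labelled layout (row labels A-H somewhere in the first
    column, column labels 1-12 in a header row) or a bare positional 8x12
    numeric block.
    """
    raw = df.copy()
    raw.columns = range(raw.shape[1])
    # labelled layout: find the row holding column labels 1..12
    first_col = raw.iloc[:, 0].astype(str).str.strip()
    row_idx = {r: i for i, r in enumerate(first_col) if r in PLATE_ROWS}
    if len(row_idx) == 8 and raw.shape[1] >= 13:
        values: dict[str, float | None] = {}
        for r, i in row_idx.items():
            for j, c in enumerate(PLATE_COLS, start=1):
                cell = raw.iat[i, j]
                values[f"{r}{c}"] = _parse_cell(cell, f"{r}{c}")
        return ODGrid(values, source_path=path, plate_id=plate_id)
    # positional layout: first 8 rows x first 12 columns
    if raw.shape[0] >= 8 and raw.shape[1] >= 12:
        values = {}
        for i, r in enumerate(PLATE_ROWS):
            for j, c in enumerate(PLATE_COLS):
                values[f"{r}{c}"] = _parse_cell(raw.iat[i, j], f"{r}{c}")
        return ODGrid(values, source_path=path, plate_id=plate_id)
    raise SpreadsheetFormatError(f"could not locate an 8x12 OD block in {path}")


def _parse_cell(cell, address: str) -> float | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    if isinstance(cell, str) and cell.strip() == "":
        return None
    try:
        v = float(cell)
    except (TypeError, ValueError) as exc:
        raise SpreadsheetFormatError(f"non-numeric OD cell at {address}: {cell!r}") from exc
    if not np.isfinite(v) or v < 0:
        raise SpreadsheetFormatError(f"invalid OD at {address}: {v!r}")
    return v


def load_od_grid(path: str | Path, plate_id: str | None = None) -> ODGrid:
    """Load an OD spreadsheet (CSV or XLSX) into an :class:`ODGrid`.

    Missing cells are recorded as missing, not zero; a non-numeric cell raises
    :class:`SpreadsheetFormatError` naming the well address.
    """
    path = Path(path)
    pid = plate_id or path.stem
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        df = pd.read_excel(path, header=None)
    else:
        df = pd.read_csv(path, header=None, skip_blank_lines=False)
    return _grid_from_frame(df, str(path), pid)


def save_od_grid(grid: ODGrid, path: str | Path) -> Path:
    """Write a labelled-layout OD grid (CSV or XLSX by extension)."""
    path = Path(path)
    data = {
        c: [grid.get(f"{r}{c}") for r in PLATE_ROWS] for c in PLATE_COLS
    }
    df = pd.DataFrame(data, index=list(PLATE_ROWS))
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path)
    else:
        df.to_csv(path)
    return path


# ---------------------------------------------------------------------------
# tagging and grouping


def tag_images_with_od(
    wells: Sequence[WellImage],
    grid: ODGrid,
    out_dir: str | Path,
    plate_id: str | None = None,
) -> list[Path]:
    """Write each well image renamed by its OD: ``<plate>_<well>_<od:.3f>.png``.

    Wells whose grid cell is missing are skipped with a log entry; a well
    label absent from the grid altogether raises :class:`MatchError`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pid = plate_id or grid.plate_id
    written: list[Path] = []
    for w in wells:
        if w.label not in grid.values:
            raise MatchError(f"well {w.label} not present in OD grid {grid.source_path}")
        od = grid.get(w.label)
        if od is None:
            logger.info("skipping well %s: OD missing from grid", w.label)
            continue
        target = out_dir / f"{pid}_{w.label}_{od:.3f}.png"
        Image.fromarray(w.pixels, mode="L").save(target)
        written.append(target)
    return written


def parse_od_from_filename(path: str | Path) -> float | None:
    """OD encoded in a tagged filename (trailing ``_<od:.3f>``), or None."""
    m = _OD_SUFFIX_RE.search(Path(path).stem)
    return float(m.group(1)) if m else None


@dataclass
class GroupResult:
    """Outcome of sorting tagged images into level folders."""

    counts: dict[int, int]
    rejects: list[Path] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + len(self.rejects)


def group_images_by_level(
    tagged_dir: str | Path,
    levels: ClassificationLevels,
    out_dir: str | Path | None = None,
    move: bool = False,
) -> GroupResult:
    """Sort OD-tagged images into ``level_<k>/`` folders by their OD interval.

    Copies by default (non-destructive); files without a parseable OD suffix
    are listed in the result's rejects, never fatal. Per-level counts plus
    rejects always sum to the input file count.
    """
    tagged_dir = Path(tagged_dir)
    out_dir = Path(out_dir) if out_dir is not None else tagged_dir
    counts = {k: 0 for k in range(1, levels.n_levels + 1)}
    rejects: list[Path] = []
    for f in sorted(tagged_dir.iterdir()):
        if not f.is_file() or f.suffix.lower() not in (".png", ".tif", ".tiff", ".jpg", ".jpeg"):
            continue
        od = parse_od_from_filename(f)
        if od is None:
            rejects.append(f)
            continue
        level = od_to_level(od, levels)
        dest = out_dir / f"level_{level}"
        dest.mkdir(parents=True, exist_ok=True)
        if move:
            shutil.move(str(f), dest / f.name)
        else:
            shutil.copy2(f, dest / f.name)
        counts[level] += 1
    if rejects:
        report = out_dir / "rejects.txt"
        report.write_text("\n".join(str(p) for p in rejects) + "\n")
    return GroupResult(counts=counts, rejects=rejects)


def make_flipped_validation_set(training_dir: str | Path, out_dir: str | Path) -> int:
    """Horizontally mirror every image of a level-sorted tree into ``out_dir``.

    Preserves the directory structure and per-level counts; applying it to its
    own output restores the original pixel content (mirroring is an
    involution). Returns the number of images written.
    """
    training_dir = Path(training_dir)
    out_dir = Path(out_dir)
    n = 0
    for f in sorted(training_dir.rglob("*")):
        if not f.is_file() or f.suffix.lower() not in (".png", ".tif", ".tiff"):
            continue
        rel = f.relative_to(training_dir)
        target = out_dir / rel
        target.parent.mkdir(parents=True, exist_ok=True)
        well = load_well_image(f)
        flipped = flip_well_image(well, "horizontal")
        Image.fromarray(flipped.pixels, mode="L").save(target)
        n += 1
    return n


# ---------------------------------------------------------------------------
# model evaluation


@dataclass
class EvaluationReport:
    """Accuracy of model-assigned levels against spectrophotometric truth.

    Per-level accuracy is stratified by the *measured* level; r_squared is the
    coefficient of determination of an ordinary least-squares fit of assigned
    on measured levels (0.0 for a constant predictor).
    """

    pairs: pd.DataFrame  # columns: plate, well, measured_od, measured_level, assigned_level, correct
    global_accuracy: float
    per_level_accuracy: dict[int, tuple[float, int]]  # level -> (accuracy, count)
    r_squared: float
    confusion: np.ndarray  # [measured-1, assigned-1] counts

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _ols_r_squared(measured: np.ndarray, assigned: np.ndarray) -> float:
    if len(measured) < 2 or np.var(measured) == 0 or np.var(assigned) == 0:
        return 0.0
    r = np.corrcoef(measured, assigned)[0, 1]
    return float(r * r)


def evaluate_model(
    clf: WellClassifier,
    eval_pairs: Sequence[tuple[WellImage, float]],
    levels: ClassificationLevels,
    plate_id: str = "eval",
) -> EvaluationReport:
    """Compare model-assigned levels with levels binned from measured ODs."""
    if not eval_pairs:
        raise EmptyEvaluationError("no (image, OD) pairs to evaluate")
    rows = []
    L = levels.n_levels
    confusion = np.zeros((L, L), dtype=int)
    for well, od in eval_pairs:
        measured = od_to_level(od, levels)
        assigned = classify_well(clf, well)
        confusion[measured - 1, assigned - 1] += 1
        rows.append((plate_id, well.label, od, measured, assigned, measured == assigned))
    df = pd.DataFrame(
        rows, columns=["plate", "well", "measured_od", "measured_level", "assigned_level", "correct"]
    )
    global_acc = float(df["correct"].mean())
    per_level: dict[int, tuple[float, int]] = {}
    for lvl, sub in df.groupby("measured_level"):
        per_level[int(lvl)] = (float(sub["correct"].mean()), len(sub))
    r2 = _ols_r_squared(df["measured_level"].to_numpy(float), df["assigned_level"].to_numpy(float))
    return EvaluationReport(
        pairs=df,
        global_accuracy=global_acc,
        per_level_accuracy=per_level,
        r_squared=r2,
        confusion=confusion,
    )


def export_evaluation(report: EvaluationReport, pairs_path: str | Path, summary_path: str | Path | None = None) -> None:
    """Write the per-pair CSV and a summary CSV of global/per-level metrics."""
    report.pairs.to_csv(pairs_path, index=False)
    if summary_path is not None:
        rows = [("global", report.global_accuracy, report.n_pairs, report.r_squared)]
        for lvl in sorted(report.per_level_accuracy):
            acc, n = report.per_level_accuracy[lvl]
            rows.append((f"level_{lvl}", acc, n, ""))
        pd.DataFrame(rows, columns=["stratum", "accuracy", "n", "r_squared"]).to_csv(
            summary_path, index=False
        )
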
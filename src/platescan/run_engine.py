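"""Run orchestration: slice and classify every well of a time-ordered scan series.

A *run* processes one plate image per timepoint (flip -> slice -> classify),
accumulating one level-versus-time series per well, and persists the whole
session as JSON. Offline runs consume a directory of previously acquired
images; "online" acquisition is abstracted behind a tiny source contract
(``next_image() -> path | None``) with directory-watching and synthetic
backends, so real scanner hardware is an extension point rather than a
dependency. Classification depends only on the model state and pixels —
timestamps and wall-clock metadata never influence the assigned levels.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterator, Protocol, Sequence

import pandas as pd

from .density_model import WellClassifier, classify_wells, load_classifier
from .errors import SchemaError
from .plate_imaging import (
    FlipAxis,
    PlateMask,
    flip_plate_image,
    load_mask,
    load_plate_image,
    slice_plate,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "platescan-session-1"

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclass(frozen=True)
class RunConfig:
    """Static configuration of a run."""

    mask_path: str = ""
    model_path: str = ""
    interval_minutes: float = 30.0
    n_timepoints: int = 1
    flip: FlipAxis = "horizontal"
    out_dir: str = ""

    def __post_init__(self) -> None:
        if self.interval_minutes <= 0:
            raise ValueError("interval_minutes must be positive")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")


@dataclass(frozen=True)
class TimePoint:
    """One acquisition: elapsed minutes = index * interval."""

    index: int
    minutes: float
    image_path: str
    missing: bool = False


@dataclass
class RunSession:
    """All results of one run; round-trips losslessly through JSON."""

    config: RunConfig
    timepoints: list[TimePoint] = field(default_factory=list)
    series: dict[str, list[int | None]] = field(default_factory=dict)
    n_levels: int = 6
    schema_version: str = SCHEMA_VERSION
    created_at: str = ""

    def __post_init__(self) -> None:
        if not self.created_at:
            self.created_at = datetime.now(timezone.utc).isoformat(timespec="seconds")

    @property
    def minutes(self) -> list[float]:
        return [tp.minutes for tp in self.timepoints]

    def validate(self) -> None:
        for label, lv in self.series.items():
            if len(lv) != len(self.timepoints):
                raise SchemaError(f"series {label} length {len(lv)} != {len(self.timepoints)} timepoints")
            for v in lv:
                if v is not None and not 1 <= v <= self.n_levels:
                    raise SchemaError(f"level {v} for well {label} outside 1..{self.n_levels}")


def _process_image(
    path: Path,
    index: int,
    config: RunConfig,
    mask: PlateMask,
    clf: WellClassifier,
    session: RunSession,
) -> None:
    """Classify one frame into the session (missing timepoint on failure)."""
    minutes = index * config.interval_minutes
    try:
        img = load_plate_image(path, timestamp=minutes)
        img = flip_plate_image(img, config.flip)
        wells = slice_plate(img, mask)
        levels = classify_wells(clf, wells)
    except Exception as exc:  # unreadable/corrupt frame: record and continue
        logger.warning("timepoint %d (%s) unreadable: %s", index, path, exc)
        session.timepoints.append(TimePoint(index, minutes, str(path), missing=True))
        for label in mask.labels:
            session.series[label].append(None)
        return
    session.timepoints.append(TimePoint(index, minutes, str(path), missing=False))
    for well, level in zip(wells, levels):
        session.series[well.label].append(level)


def _new_session(config: RunConfig, mask: PlateMask, clf: WellClassifier) -> RunSession:
    return RunSession(
        config=config,
        series={label: [] for label in mask.labels},
        n_levels=clf.levels.n_levels,
    )


def run_offline(
    image_dir: str | Path,
    config: RunConfig,
    mask: PlateMask | None = None,
    clf: WellClassifier | None = None,
    session: RunSession | None = None,
) -> RunSession:
    """Process a directory of acquired images in lexicographic filename order.

    ``mask``/``clf`` default to loading ``config.mask_path`` and
    ``config.model_path``. Passing a previous ``session`` resumes it: frames
    whose paths were already processed are skipped, new ones are appended.
    """
    image_dir = Path(image_dir)
    mask = mask if mask is not None else load_mask(config.mask_path)
    clf = clf if clf is not None else load_classifier(config.model_path)
    files = sorted(p for p in image_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no images found in {image_dir}")
    if session is None:
        session = _new_session(config, mask, clf)
    seen = {tp.image_path for tp in session.timepoints}
    index = len(session.timepoints)
    for path in files:
        if str(path) in seen:
            continue
        _process_image(path, index, config, mask, clf, session)
        index += 1
    session.validate()
    return session


class AcquisitionSource(Protocol):
    """Minimal acquisition contract replacing scanner hardware control."""

    def next_image(self) -> str | Path | None:
        """Path of the next acquired frame, or None when exhausted."""
        ...


class DirectorySource:
    """Yields image files from a directory as they appear, in sorted order."""

    def __init__(self, directory: str | Path, poll_seconds: float = 0.0, max_polls: int = 1):
        self.directory = Path(directory)
        self.poll_seconds = poll_seconds
        self.max_polls = max_polls
        self._served: set[str] = set()

    def next_image(self) -> Path | None:
        for _ in range(max(1, self.max_polls)):
            fresh = sorted(
                p
                for p in self.directory.iterdir()
                if p.suffix.lower() in IMAGE_SUFFIXES and str(p) not in self._served
            )
            if fresh:
                self._served.add(str(fresh[0]))
                return fresh[0]
            if self.poll_seconds:
                time.sleep(self.poll_seconds)
        return None


class SyntheticSource:
    """Serves a pre-built list of frame paths (e.g. from synth_data.generate_run)."""

    def __init__(self, paths: Sequence[str | Path]):
        self._paths = [Path(p) for p in paths]
        self._i = 0

    def next_image(self) -> Path | None:
        if self._i >= len(self._paths):
            return None
        p = self._paths[self._i]
        self._i += 1
        return p


def acquire_series(source: AcquisitionSource, config: RunConfig) -> Iterator[TimePoint]:
    """Yield up to ``n_timepoints`` timepoints from an acquisition source.

    Warns and stops early if the source is exhausted before the configured
    count (truncated session).
    """
    for index in range(config.n_timepoints):
        path = source.next_image()
        if path is None:
            warnings.warn(
                f"acquisition source exhausted after {index} of {config.n_timepoints} frames",
                stacklevel=2,
            )
            return
        yield TimePoint(index, index * config.interval_minutes, str(path))


def run_acquisition(
    source: AcquisitionSource,
    config: RunConfig,
    mask: PlateMask | None = None,
    clf: WellClassifier | None = None,
) -> RunSession:
    """Consume an acquisition source frame-by-frame into a session.

    Produces results identical to :func:`run_offline` over the same frames.
    """
    mask = mask if mask is not None else load_mask(config.mask_path)
    clf = clf if clf is not None else load_classifier(config.model_path)
    session = _new_session(config, mask, clf)
    for tp in acquire_series(source, config):
        _process_image(Path(tp.image_path), tp.index, config, mask, clf, session)
    session.validate()
    return session


# ---------------------------------------------------------------------------
# persistence and export


def save_session(session: RunSession, path: str | Path) -> Path:
    """Write the session JSON (sorted keys; byte-stable for equal sessions)."""
    session.validate()
    path = Path(path)
    payload = {
        "schema_version": session.schema_version,
        "created_at": session.created_at,
        "n_levels": session.n_levels,
        "config": asdict(session.config),
        "timepoints": [asdict(tp) for tp in session.timepoints],
        "series": {k: session.series[k] for k in sorted(session.series)},
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path


def load_session(path: str | Path) -> RunSession:
    """Load and validate a session JSON; unknown schema versions are rejected."""
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unknown session schema {payload.get('schema_version')!r}")
    session = RunSession(
        config=RunConfig(**payload["config"]),
        timepoints=[TimePoint(**tp) for tp in payload["timepoints"]],
        series={k: [None if v is None else int(v) for v in vs] for k, vs in payload["series"].items()},
        n_levels=int(payload.get("n_levels", 6)),
        schema_version=payload["schema_version"],
        created_at=payload.get("created_at", ""),
    )
    try:
        session.validate()
    except SchemaError:
        raise
    return session


def export_table(session: RunSession, path: str | Path) -> Path:
    """Export the wide level table: one row per timepoint, ``minutes`` first.

    Missing classifications become empty cells (not zeros).
    """
    labels = sorted(session.series, key=lambda l: (ord(l[0]), int(l[1:])))
    data = {"minutes": session.minutes}
    for label in labels:
        data[label] = [v if v is not None else pd.NA for v in session.series[label]]
    df = pd.DataFrame(data)
    df.to_csv(path, index=False)
    return Path(path)


def import_table(path: str | Path) -> tuple[list[float], dict[str, list[int | None]]]:
    """Parse an exported table back into (minutes, well -> levels)."""
    df = pd.read_csv(path)
    minutes = df["minutes"].astype(float).tolist()
    series: dict[str, list[int | None]] = {}
    for col in df.columns:
        if col == "minutes":
            continue
        series[col] = [None if pd.isna(v) else int(v) for v in df[col]]
    return minutes, series
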
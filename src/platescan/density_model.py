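"""Density levels and the well-image classifier.

Discrete *density levels* stand in for OD620 intervals: the default table has
six levels (level 1: <0.06, 2: [0.06-0.15), 3: [0.15-0.25), 4: [0.25-0.35),
5: [0.35-0.60), 6: >=0.60), a partition of [0, inf) with left-closed,
right-open bins. OD values are used as read, without blank subtraction.

Classification maps a cropped well raster to a level. The optical principle:
under a black cover, a clear well shows a crisp bright-ring/central-shadow
pattern that fades as turbidity rises, so a handful of contrast statistics
carry the density signal. The default backend is a shallow decision tree over
those statistics; any object with ``fit``/``predict`` over the same feature
layout can be plugged in instead (the original tool used a CNN).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier
from sklearn.model_selection import train_test_split

from .errors import LevelFormatError, ModelStateError, TrainingDataError
from .plate_imaging import WellImage, load_well_image

#: Printed default OD620 intervals for the six density levels.
DEFAULT_LEVEL_BOUNDS = (0.06, 0.15, 0.25, 0.35, 0.60)

FEATURE_NAMES = (
    "mean_intensity",
    "std_intensity",
    "radial_contrast",
    "edge_gradient_mean",
    "q10",
    "q50",
    "q90",
)

_MODEL_SCHEMA = "platescan-model-1"
# fixed archive member date so identical training runs produce identical bytes
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


@dataclass(frozen=True)
class ClassificationLevels:
    """Ordered, contiguous OD620 intervals defining density levels 1..L.

    ``bounds`` are the L-1 interior cut points; level k covers
    [bounds[k-2], bounds[k-1]) with an implicit 0 below and +inf above.
    """

    bounds: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.size == 0:
            raise LevelFormatError("at least two levels (one cut point) required")
        if not np.all(np.isfinite(b)) or np.any(b <= 0):
            raise LevelFormatError("interior cut points must be finite and positive")
        if np.any(np.diff(b) <= 0):
            raise LevelFormatError("cut points must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.bounds) + 1

    def interval(self, level: int) -> tuple[float, float]:
        """[lower, upper) of a level; level 1 starts at 0, the last is unbounded."""
        if not 1 <= level <= self.n_levels:
            raise ValueError(f"level {level} outside 1..{self.n_levels}")
        lower = 0.0 if level == 1 else self.bounds[level - 2]
        upper = np.inf if level == self.n_levels else self.bounds[level - 1]
        return lower, upper

    @property
    def levels(self) -> list[tuple[int, float, float]]:
        return [(k, *self.interval(k)) for k in range(1, self.n_levels + 1)]


def default_levels() -> ClassificationLevels:
    """The shipped six-level table."""
    return ClassificationLevels(DEFAULT_LEVEL_BOUNDS)


def load_levels(path: str | Path) -> ClassificationLevels:
    """Load a levels CSV (header ``level,lower,upper``; last upper ``inf``).

    Intervals must be contiguous ([0, b1), [b1, b2), ..., [b_{L-1}, inf)) and
    level ids consecutive from 1; gaps or overlaps are rejected.
    """
    df = pd.read_csv(path)
    expected = ["level", "lower", "upper"]
    if list(df.columns[:3]) != expected:
        raise LevelFormatError(f"levels header must be {','.join(expected)}")
    df = df.sort_values("level").reset_index(drop=True)
    if list(df["level"]) != list(range(1, len(df) + 1)):
        raise LevelFormatError("level ids must be consecutive integers starting at 1")
    lowers = df["lower"].astype(float).to_numpy()
    uppers = df["upper"].astype(float).to_numpy()
    if lowers[0] != 0.0:
        raise LevelFormatError("level 1 must start at 0")
    if not np.isinf(uppers[-1]):
        raise LevelFormatError("last level must be unbounded (upper = inf)")
    for i in range(len(df) - 1):
        if uppers[i] != lowers[i + 1]:
            raise LevelFormatError(
                f"gap or overlap between level {i + 1} (upper {uppers[i]}) "
                f"and level {i + 2} (lower {lowers[i + 1]})"
            )
    return ClassificationLevels(tuple(uppers[:-1]))


def save_levels(levels: ClassificationLevels, path: str | Path) -> Path:
    path = Path(path)
    rows = [(k, lo, "inf" if np.isinf(up) else up) for k, lo, up in levels.levels]
    pd.DataFrame(rows, columns=["level", "lower", "upper"]).to_csv(path, index=False)
    return path


def od_to_level(od: float, levels: ClassificationLevels) -> int:
    """Assign the density level whose [lower, upper) interval contains ``od``."""
    od = float(od)
    if not np.isfinite(od) or od < 0:
        raise ValueError(f"OD must be finite and non-negative, got {od}")
    # bounds sorted ascending; 'right' side makes bins left-closed/right-open
    return int(np.searchsorted(levels.bounds, od, side="right")) + 1


def od_to_level_array(od: np.ndarray, levels: ClassificationLevels) -> np.ndarray:
    od = np.asarray(od, dtype=float)
    if not np.all(np.isfinite(od)) or np.any(od < 0):
        raise ValueError("OD values must be finite and non-negative")
    return np.searchsorted(levels.bounds, od, side="right").astype(int) + 1


# ---------------------------------------------------------------------------
# feature extraction


def extract_features(well: WellImage) -> np.ndarray:
    """Turbidity feature vector of a well raster (see FEATURE_NAMES).

    radial_contrast is the mean intensity over a ring annulus (0.55-0.95 of
    the inscribed radius) minus the mean over the central disk (<0.35 R) —
    the bright-ring-vs-shadow pattern that fades with turbidity. Deterministic
    and independent of which plate the well came from.
    """
    px = well.pixels.astype(np.float64)
    if px.size == 0:
        raise ValueError("empty well raster")
    h, w = px.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    radius = min(h, w) / 2.0
    ring = (r >= 0.55 * radius) & (r <= 0.95 * radius)
    center = r < 0.35 * radius
    ring_mean = px[ring].mean() if ring.any() else px.mean()
    center_mean = px[center].mean() if center.any() else px.mean()
    gy, gx = np.gradient(px)
    grad_mean = float(np.hypot(gy, gx).mean())
    q10, q50, q90 = np.percentile(px, [10, 50, 90])
    return np.array(
        [px.mean(), px.std(), ring_mean - center_mean, grad_mean, q10, q50, q90],
        dtype=np.float64,
    )


def extract_features_batch(wells: Sequence[WellImage]) -> np.ndarray:
    return np.vstack([extract_features(w) for w in wells])


# ---------------------------------------------------------------------------
# classifier


@dataclass
class WellClassifier:
    """A trained level classifier over :data:`FEATURE_NAMES` features.

    ``kind`` is "shallow" for the built-in tree ensemble; external backends
    keep their own kind tag. Serializes to a single ZIP archive (parameters +
    levels table + feature spec) and reloads bit-compatibly.
    """

    kind: str
    levels: ClassificationLevels
    estimator: object | None = None
    feature_spec: tuple[str, ...] = FEATURE_NAMES
    metadata: dict = field(default_factory=dict)

    def _check_trained(self) -> None:
        if self.estimator is None or not hasattr(self.estimator, "predict"):
            raise ModelStateError("classifier has not been trained")

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        self._check_trained()
        pred = np.asarray(self.estimator.predict(np.atleast_2d(X)), dtype=int)
        return np.clip(pred, 1, self.levels.n_levels)


def classify_well(clf: WellClassifier, well: WellImage) -> int:
    """Density level of one well image; pure function of (model state, pixels)."""
    return int(clf.predict_features(extract_features(well)[None, :])[0])


def classify_wells(clf: WellClassifier, wells: Sequence[WellImage]) -> list[int]:
    if not wells:
        return []
    return [int(v) for v in clf.predict_features(extract_features_batch(wells))]


def _shallow_estimator(seed: int) -> DecisionTreeClassifier:
    # a shallow tree: axis-aligned midpoint thresholds suit a signal that is
    # monotone in OD; deterministic given the seed
    return DecisionTreeClassifier(max_depth=12, min_samples_leaf=1, random_state=seed)


def train_classifier_from_features(
    X: np.ndarray,
    y: np.ndarray,
    levels: ClassificationLevels,
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> WellClassifier:
    """Fit the shallow classifier on precomputed features; y holds level ids."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    present = np.unique(y)
    if present.size < 2:
        raise TrainingDataError("need training images for at least 2 levels")
    counts = {int(k): int((y == k).sum()) for k in present}
    if min(counts.values()) < 5:
        lacking = [k for k, n in counts.items() if n < 5]
        raise TrainingDataError(f"need >=5 images per level; too few for levels {lacking}")
    Xtr, Xho, ytr, yho = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    est = _shallow_estimator(seed)
    est.fit(Xtr, ytr)
    holdout_acc = float((est.predict(Xho) == yho).mean())
    # refit on everything so the shipped model uses all data
    est_final = _shallow_estimator(seed)
    est_final.fit(X, y)
    meta = {
        "seed": int(seed),
        "n_per_level": counts,
        "holdout_accuracy": holdout_acc,
        "holdout_fraction": holdout_fraction,
    }
    return WellClassifier(kind="shallow", levels=levels, estimator=est_final, metadata=meta)


def train_classifier(
    training_dirs: Mapping[int, str | Path],
    levels: ClassificationLevels,
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> WellClassifier:
    """Train from a mapping level id -> directory of well images (PNG/TIFF).

    Reports a held-out accuracy in ``metadata['holdout_accuracy']``;
    deterministic for a fixed seed and file set.
    """
    feats, labels = [], []
    for level, d in sorted(training_dirs.items()):
        d = Path(d)
        files = sorted(p for p in d.glob("*") if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise TrainingDataError(f"no training images for level {level} in {d}")
        for p in files:
            feats.append(extract_features(load_well_image(p)))
            labels.append(level)
    return train_classifier_from_features(
        np.vstack(feats), np.array(labels), levels, seed=seed, holdout_fraction=holdout_fraction
    )


def train_classifier_from_tree(
    root: str | Path, levels: ClassificationLevels, seed: int = 0
) -> WellClassifier:
    """Train from a ``level_<k>/`` directory tree (the grouping-step layout)."""
    root = Path(root)
    dirs = {}
    for d in sorted(root.glob("level_*")):
        try:
            dirs[int(d.name.split("_")[1])] = d
        except (IndexError, ValueError):
            continue
    if not dirs:
        raise TrainingDataError(f"no level_<k> subdirectories under {root}")
    return train_classifier(dirs, levels, seed=seed)


# ---------------------------------------------------------------------------
# serialization: one ZIP archive (model.json + levels.csv + feature_spec.json)


def _tree_to_json(est: DecisionTreeClassifier) -> dict:
    tr = est.tree_
    tree = {
        "children_left": tr.children_left.tolist(),
        "children_right": tr.children_right.tolist(),
        "feature": tr.feature.tolist(),
        "threshold": tr.threshold.tolist(),
        "value": tr.value.tolist(),
    }
    return {"classes": est.classes_.tolist(), "trees": [tree]}


class _JsonForest:
    """Prediction-only tree(s) reconstructed from the archived tables."""

    def __init__(self, payload: dict):
        self.classes_ = np.asarray(payload["classes"])
        self._trees = payload["trees"]

    def _predict_tree(self, tree: dict, X: np.ndarray) -> np.ndarray:
        left = tree["children_left"]
        right = tree["children_right"]
        feat = tree["feature"]
        thr = tree["threshold"]
        value = tree["value"]
        out = np.empty((X.shape[0], len(self.classes_)))
        for i, row in enumerate(X):
            node = 0
            while left[node] != -1:
                node = left[node] if row[feat[node]] <= thr[node] else right[node]
            out[i] = value[node][0]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        proba = sum(self._predict_tree(t, X) for t in self._trees)
        return self.classes_[np.argmax(proba, axis=1)]


def save_classifier(clf: WellClassifier, path: str | Path) -> Path:
    """Write the classifier as a single portable ZIP archive."""
    clf._check_trained()
    path = Path(path)
    if isinstance(clf.estimator, DecisionTreeClassifier):
        params = _tree_to_json(clf.estimator)
    elif isinstance(clf.estimator, _JsonForest):
        params = {"classes": clf.estimator.classes_.tolist(), "trees": clf.estimator._trees}
    else:
        raise ModelStateError(
            f"only the shallow backend serializes to the archive format, got {type(clf.estimator)}"
        )
    model = {"schema": _MODEL_SCHEMA, "kind": clf.kind, "metadata": clf.metadata, "params": params}
    levels_csv = io.StringIO()
    rows = [(k, lo, "inf" if np.isinf(up) else up) for k, lo, up in clf.levels.levels]
    pd.DataFrame(rows, columns=["level", "lower", "upper"]).to_csv(levels_csv, index=False)
    spec = {"features": list(clf.feature_spec)}
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, text in (
            ("model.json", json.dumps(model, sort_keys=True)),
            ("levels.csv", levels_csv.getvalue()),
            ("feature_spec.json", json.dumps(spec, sort_keys=True)),
        ):
            zi = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            zi.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(zi, text)
    return path


def load_classifier(path: str | Path) -> WellClassifier:
    """Reload an archived classifier; predictions match the saved model exactly."""
    with zipfile.ZipFile(path) as zf:
        model = json.loads(zf.read("model.json"))
        spec = json.loads(zf.read("feature_spec.json"))
        levels_df = pd.read_csv(io.BytesIO(zf.read("levels.csv")))
    if model.get("schema") != _MODEL_SCHEMA:
        raise ModelStateError(f"unknown model schema {model.get('schema')!r}")
    uppers = levels_df.sort_values("level")["upper"].astype(float).to_numpy()
    levels = ClassificationLevels(tuple(uppers[:-1]))
    return WellClassifier(
        kind=model["kind"],
        levels=levels,
        estimator=_JsonForest(model["params"]),
        feature_spec=tuple(spec["features"]),
        metadata=model.get("metadata", {}),
    )
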
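"""Growth quantification: trapezoidal AUC, Hill dose-response and Gompertz fits.

The area under a level-versus-time growth curve summarises overall growth in a
single scalar. With density levels f(t_i) in 1..L at unit-spaced timepoints,
the 2-point closed Newton-Cotes (trapezoidal) rule with the resting level
subtracted gives

    AUC = sum_{i=0}^{n-1} [ (f(t_i) + f(t_{i+1})) / 2 - baseline ]

so a well that never grows (constantly at level 1, the default baseline)
scores exactly 0.

Antibiotic action is quantified by fitting AUC against dose with a
pharmacodynamic Hill function on the log2 concentration axis x:

    AUC(x) = AUC_max - E_m * (x/EC50)^k / (1 + (x/EC50)^k)

where AUC_max is the no-antibiotic AUC, E_m the maximal AUC reduction, EC50
the half-effect point (on the log2 axis) and k the Hill coefficient
(sigmoidicity). Individual curves can additionally be fitted with the
modified Gompertz model of Zwietering et al. (asymptote A, maximum growth
rate mu_m, lag time lambda):

    y(t) = baseline + A * exp(-exp(mu_m * e / A * (lambda - t) + 1))
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateFitWarning, InsufficientDataError, UnderdeterminedError
from .run_engine import RunSession

__all__ = [
    "GrowthCurve",
    "AUCResult",
    "HillFitResult",
    "GompertzFitResult",
    "DoseResponsePoint",
    "DoseResponseResult",
    "compute_auc",
    "hill_curve",
    "fit_hill",
    "gompertz_curve",
    "fit_gompertz",
    "build_dose_response",
]


@dataclass(frozen=True)
class GrowthCurve:
    """Per-well density levels over time; ``minutes`` optional, index-spaced otherwise."""

    levels: tuple[float | None, ...]
    minutes: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.minutes is not None and len(self.minutes) != len(self.levels):
            raise ValueError("minutes and levels must have equal length")


@dataclass(frozen=True)
class AUCResult:
    auc: float
    n_intervals: int
    baseline: float = 1.0


@dataclass(frozen=True)
class HillFitResult:
    auc_max: float
    e_m: float
    ec50: float
    k: float
    residual_sse: float
    converged: bool
    anchored: bool = False


@dataclass(frozen=True)
class GompertzFitResult:
    A: float
    mu_m: float
    lam: float
    baseline: float
    residual_sse: float
    converged: bool


@dataclass(frozen=True)
class DoseResponsePoint:
    concentration: float  # ug/L; > 0 for fitted points
    x: float  # log2(concentration)
    auc: AUCResult


@dataclass
class DoseResponseResult:
    antibiotic: str
    points: list[DoseResponsePoint]
    control_auc: AUCResult | None
    fit: HillFitResult | None


# ---------------------------------------------------------------------------
# AUC


def _clean_levels(levels: Sequence[float | None], bridge_missing: bool) -> np.ndarray:
    """Trim missing ends; linearly bridge interior gaps (no extrapolation)."""
    vals = np.array([np.nan if v is None else float(v) for v in levels], dtype=float)
    valid = np.flatnonzero(~np.isnan(vals))
    if valid.size < 2:
        raise InsufficientDataError("need at least 2 valid timepoints")
    vals = vals[valid[0] : valid[-1] + 1]
    if np.isnan(vals).any():
        if not bridge_missing:
            raise InsufficientDataError("curve has interior gaps and bridging is disabled")
        idx = np.arange(len(vals))
        good = ~np.isnan(vals)
        vals[~good] = np.interp(idx[~good], idx[good], vals[good])
    return vals


def compute_auc(
    curve: GrowthCurve | Sequence[float | None],
    baseline: float = 1.0,
    bridge_missing: bool = True,
) -> AUCResult:
    """Trapezoidal AUC of (level - baseline) over unit-spaced timepoints.

    Interior missing levels are bridged by linear interpolation; missing ends
    are trimmed, never extrapolated.
    """
    levels = curve.levels if isinstance(curve, GrowthCurve) else curve
    vals = _clean_levels(levels, bridge_missing)
    n_intervals = len(vals) - 1
    auc = float(np.sum((vals[:-1] + vals[1:]) / 2.0 - baseline))
    return AUCResult(auc=auc, n_intervals=n_intervals, baseline=baseline)


# ---------------------------------------------------------------------------
# Hill dose-response


def hill_curve(x: np.ndarray, auc_max: float, e_m: float, ec50: float, k: float) -> np.ndarray:
    """Hill response at log2-dose x; approaches auc_max as x->0+, auc_max-e_m as x->inf."""
    x = np.asarray(x, dtype=float)
    ratio = np.power(x / ec50, k)
    return auc_max - e_m * ratio / (1.0 + ratio)


def _hill_residuals(theta: np.ndarray, x: np.ndarray, y: np.ndarray, anchor: float | None):
    if anchor is None:
        auc_max, e_m, ec50, k = theta
    else:
        auc_max = anchor
        e_m, ec50, k = theta
    return hill_curve(x, auc_max, e_m, ec50, k) - y


def fit_hill(
    points: Sequence[DoseResponsePoint],
    auc_max_anchor: AUCResult | float | None = None,
    seed: int = 0,
) -> HillFitResult:
    """Bounded nonlinear least-squares fit of the Hill dose-response model.

    Fits (AUC_max, E_m, EC50, k), or (E_m, EC50, k) when AUC_max is anchored
    to the zero-antibiotic control AUC. Uses multi-start initialization (5
    deterministic starts spread over the dose range); requires >= 4 distinct
    positive doses unanchored (>= 3 anchored). A flat response yields E_m ~ 0
    with a :class:`DegenerateFitWarning`.
    """
    pts = sorted(points, key=lambda p: p.x)
    x = np.array([p.x for p in pts], dtype=float)
    y = np.array([p.auc.auc for p in pts], dtype=float)
    if np.any(np.array([p.concentration for p in pts]) <= 0):
        raise ValueError("dose-response points must have positive concentrations")
    anchor = None
    if auc_max_anchor is not None:
        anchor = auc_max_anchor.auc if isinstance(auc_max_anchor, AUCResult) else float(auc_max_anchor)
    n_free = 3 if anchor is not None else 4
    if len(np.unique(x)) < n_free:
        raise UnderdeterminedError(
            f"need >= {n_free} distinct positive doses for {n_free} free parameters"
        )

    y_top = anchor if anchor is not None else float(np.max(y))
    span = float(np.max(y) - np.min(y))
    if span <= 1e-12 and (anchor is None or abs(anchor - y[0]) <= 1e-12):
        warnings.warn("flat dose-response; no measurable effect", DegenerateFitWarning)
        return HillFitResult(
            auc_max=y_top,
            e_m=0.0,
            ec50=float(np.median(x)),
            k=1.0,
            residual_sse=float(np.sum((y - y_top) ** 2)),
            converged=True,
            anchored=anchor is not None,
        )

    e_m0 = max(span, y_top - float(np.min(y)), 1e-6)
    x_lo, x_hi = float(np.min(x)), float(np.max(x))
    # multi-start: log-spaced half-effect candidates well beyond the sampled
    # dose range on both sides, crossed with a spread of sigmoidicities
    ec50_starts = np.geomspace(max(x_lo / 16.0, 1e-2), 2.0 * max(x_hi, 1.0), 6)
    k_starts = (0.5, 1.0, 2.0, 4.0, 8.0)
    # generous amplitude bounds: with a half-effect point below the sampled
    # dose range the plateau AUC_max can sit far above the observed maximum
    scale = max(float(np.max(np.abs(y))), abs(y_top), 1e-3)
    em_ub = 50.0 * scale
    if anchor is None:
        lb = [0.0, 0.0, 1e-6, 1e-3]
        ub = [50.0 * scale, em_ub, max(10.0 * x_hi, 1.0), 20.0]
    else:
        lb = [0.0, 1e-6, 1e-3]
        ub = [em_ub, max(10.0 * x_hi, 1.0), 20.0]

    best = None
    from itertools import product

    for ec50_0, k_0 in product(ec50_starts, k_starts):
        theta0 = [y_top, e_m0, ec50_0, k_0] if anchor is None else [e_m0, ec50_0, k_0]
        theta0 = np.clip(theta0, lb, ub)
        try:
            res = least_squares(
                _hill_residuals, theta0, args=(x, y, anchor), bounds=(lb, ub), method="trf"
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return HillFitResult(y_top, e_m0, float(np.median(x)), 1.0, math.inf, converged=False,
                             anchored=anchor is not None)
    theta = best.x
    if anchor is None:
        auc_max, e_m, ec50, k = theta
    else:
        auc_max = anchor
        e_m, ec50, k = theta
    sse = float(2.0 * best.cost)
    if e_m <= max(1e-6, 1e-3 * abs(y_top)):
        warnings.warn("fitted maximal effect is ~0 (flat response)", DegenerateFitWarning)
    return HillFitResult(
        auc_max=float(auc_max),
        e_m=float(e_m),
        ec50=float(ec50),
        k=float(k),
        residual_sse=sse,
        converged=bool(best.success),
        anchored=anchor is not None,
    )


# ---------------------------------------------------------------------------
# Gompertz


def gompertz_curve(
    t: np.ndarray, A: float, mu_m: float, lam: float, baseline: float = 1.0
) -> np.ndarray:
    """Modified Gompertz growth curve (Zwietering parameterization)."""
    t = np.asarray(t, dtype=float)
    if A <= 0:
        return np.full_like(t, baseline)
    return baseline + A * np.exp(-np.exp(mu_m * math.e / A * (lam - t) + 1.0))


def fit_gompertz(
    curve: GrowthCurve | Sequence[float | None],
    minutes: Sequence[float] | None = None,
    baseline: float = 1.0,
    seed: int = 0,
) -> GompertzFitResult:
    """Least-squares fit of the modified Gompertz model to a growth curve.

    ``minutes`` defaults to the curve's own time axis (or unit spacing).
    Multi-start over lag/rate heuristics; a flat curve yields A ~ 0 with a
    :class:`DegenerateFitWarning` and is flagged as not converged.
    """
    if isinstance(curve, GrowthCurve):
        levels = curve.levels
        if minutes is None and curve.minutes is not None:
            minutes = curve.minutes
    else:
        levels = tuple(curve)
    y_all = np.array([np.nan if v is None else float(v) for v in levels], dtype=float)
    t_all = (
        np.asarray(minutes, dtype=float) if minutes is not None else np.arange(len(y_all), dtype=float)
    )
    good = ~np.isnan(y_all)
    y, t = y_all[good], t_all[good]
    if len(y) < 5:
        raise InsufficientDataError("need >= 5 timepoints for a Gompertz fit")

    span = float(np.max(y) - np.min(y))
    if span <= 1e-12:
        warnings.warn("flat growth curve; degenerate Gompertz fit (A ~ 0)", DegenerateFitWarning)
        sse = float(np.sum((y - baseline) ** 2))
        return GompertzFitResult(A=0.0, mu_m=0.0, lam=0.0, baseline=baseline, residual_sse=sse,
                                 converged=False)

    A0 = max(span, 1e-6)
    dt = np.diff(t)
    slopes = np.diff(y) / np.where(dt == 0, 1, dt)
    mu0 = max(float(np.max(slopes)), 1e-6)
    # lag heuristic: where the curve first exceeds 10% of its rise
    rise = y - float(np.min(y))
    above = np.flatnonzero(rise > 0.1 * span)
    lam0 = float(t[above[0]]) if above.size else float(t[0])
    t_span = float(t[-1] - t[0]) or 1.0

    def resid(theta):
        A, mu_m, lam = theta
        return gompertz_curve(t, A, mu_m, lam, baseline) - y

    lb = [1e-9, 1e-9, 0.0]
    ub = [10.0 * A0 + 1.0, 100.0 * mu0, float(t[-1]) + t_span]
    starts = [
        (A0, mu0, lam0),
        (A0, mu0 / 4.0, max(lam0 - t_span * 0.1, 0.0)),
        (A0 * 1.5, mu0 * 2.0, lam0 + t_span * 0.05),
        (A0, mu0, 0.0),
        (A0 * 0.5, mu0, lam0),
    ]
    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lb, ub)
        try:
            res = least_squares(resid, theta0, bounds=(lb, ub), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return GompertzFitResult(A0, mu0, lam0, baseline, math.inf, converged=False)
    A, mu_m, lam = best.x
    return GompertzFitResult(
        A=float(A),
        mu_m=float(mu_m),
        lam=float(lam),
        baseline=baseline,
        residual_sse=float(2.0 * best.cost),
        converged=bool(best.success),
    )


# ---------------------------------------------------------------------------
# dose-response assembly from a run session


def build_dose_response(
    session: RunSession,
    layout: Mapping[str, tuple[str, float]],
    at_hours: float = 46.0,
    baseline: float = 1.0,
    seed: int = 0,
) -> dict[str, DoseResponseResult]:
    """Per-antibiotic dose-response from a run session and a plate layout.

    ``layout`` maps well label -> (antibiotic name, concentration in ug/L);
    concentration 0 marks antibiotic-free control wells, whose mean AUC
    anchors AUC_max. AUC is computed over timepoints up to ``at_hours``. An
    antibiotic with fewer than 4 distinct positive doses is returned with its
    points but without a fit.
    """
    minutes = np.asarray(session.minutes, dtype=float)
    keep = minutes <= at_hours * 60.0 + 1e-9
    if keep.sum() < 2:
        raise InsufficientDataError(f"session does not cover {at_hours} h")

    by_drug: dict[str, list[tuple[float, AUCResult]]] = {}
    controls: dict[str, list[AUCResult]] = {}
    global_controls: list[AUCResult] = []
    for well, (drug, conc) in layout.items():
        if well not in session.series:
            raise KeyError(f"layout well {well} not present in session")
        levels = [v for v, k in zip(session.series[well], keep) if k]
        auc = compute_auc(levels, baseline=baseline)
        if conc <= 0:
            if drug:
                controls.setdefault(drug, []).append(auc)
            global_controls.append(auc)
        else:
            by_drug.setdefault(drug, []).append((conc, auc))

    results: dict[str, DoseResponseResult] = {}
    for drug, pairs in sorted(by_drug.items()):
        pairs.sort(key=lambda p: p[0])
        points = [
            DoseResponsePoint(concentration=c, x=math.log2(c), auc=a) for c, a in pairs
        ]
        ctrl_pool = controls.get(drug) or global_controls
        control_auc = None
        if ctrl_pool:
            control_auc = AUCResult(
                auc=float(np.mean([a.auc for a in ctrl_pool])),
                n_intervals=ctrl_pool[0].n_intervals,
                baseline=baseline,
            )
        fit = None
        n_doses = len({p.concentration for p in points})
        if n_doses >= 4:
            try:
                fit = fit_hill(points, auc_max_anchor=control_auc, seed=seed)
            except UnderdeterminedError:
                fit = None
        results[drug] = DoseResponseResult(
            antibiotic=drug, points=points, control_auc=control_auc, fit=fit
        )
    if not by_drug and global_controls:
        # control-only plate: report the AUC_max estimate without a fit
        results[""] = DoseResponseResult(
            antibiotic="",
            points=[],
            control_auc=AUCResult(
                auc=float(np.mean([a.auc for a in global_controls])),
                n_intervals=global_controls[0].n_intervals,
                baseline=baseline,
            ),
            fit=None,
        )
    return results


def load_layout(path) -> dict[str, tuple[str, float]]:
    """Read a plate-layout CSV (header ``well,antibiotic,concentration_ugL``)."""
    import pandas as pd

    df = pd.read_csv(path)
    expected = ["well", "antibiotic", "concentration_ugL"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"layout header must be {','.join(expected)}")
    out = {}
    for rec in df.itertuples(index=False):
        drug = "" if pd.isna(rec.antibiotic) else str(rec.antibiotic)
        out[str(rec.well)] = (drug, float(rec.concentration_ugL))
    return out


def save_fit_report(results: Mapping[str, DoseResponseResult], path) -> None:
    """One row per antibiotic: ``antibiotic,auc_max,e_m,ec50,k,sse,converged``."""
    import pandas as pd

    rows = []
    for drug, res in sorted(results.items()):
        if res.fit is None:
            rows.append((drug, res.control_auc.auc if res.control_auc else "", "", "", "", "", False))
        else:
            f = res.fit
            rows.append((drug, f.auc_max, f.e_m, f.ec50, f.k, f.residual_sse, f.converged))
    pd.DataFrame(
        rows, columns=["antibiotic", "auc_max", "e_m", "ec50", "k", "sse", "converged"]
    ).to_csv(path, index=False)
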
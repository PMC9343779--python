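"""Trapezoidal AUC, Hill dose-response fitting and Gompertz growth fitting."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platescan.errors import (
    DegenerateFitWarning,
    InsufficientDataError,
    UnderdeterminedError,
)
from platescan.growth_analysis import (
    AUCResult,
    DoseResponsePoint,
    build_dose_response,
    compute_auc,
    fit_gompertz,
    fit_hill,
    gompertz_curve,
    hill_curve,
    load_layout,
    save_fit_report,
)
from platescan.run_engine import RunConfig, RunSession, TimePoint


def dense_trapezoid_oracle(levels, baseline=1.0, per_interval=200):
    """Brute-force AUC: dense-grid trapezoid of the piecewise-linear interpolant.

    The fine grid subdivides every unit interval and contains each knot, so
    the numeric trapezoid is exact for the interpolant up to rounding.
    """
    idx = np.arange(len(levels), dtype=float)
    n = len(levels) - 1
    fine = np.concatenate(
        [np.linspace(i, i + 1, per_interval + 1)[:-1] for i in range(n)] + [[float(n)]]
    )
    interp = np.interp(fine, idx, np.asarray(levels, dtype=float))
    return np.trapezoid(interp - baseline, fine)


def dr_points(concs, aucs):
    return [
        DoseResponsePoint(c, math.log2(c), AUCResult(auc=a, n_intervals=92))
        for c, a in zip(concs, aucs)
    ]


class TestAUC:
    def test_no_growth_scores_zero(self):
        assert compute_auc([1, 1, 1, 1]).auc == 0.0

    def test_single_interval_hand_value(self):
        # (1 + 6)/2 - 1 = 2.5
        assert compute_auc([1, 6]).auc == 2.5

    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            levels = rng.integers(1, 7, size=rng.integers(2, 40)).tolist()
            assert compute_auc(levels).auc == pytest.approx(
                dense_trapezoid_oracle(levels), abs=1e-9
            )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(1, 6), min_size=2, max_size=30),
        st.floats(-3, 3, allow_nan=False),
    )
    def test_translation_equivariance(self, levels, c):
        base = compute_auc(levels, baseline=1.0).auc
        shifted = compute_auc([v + c for v in levels], baseline=1.0).auc
        assert shifted == pytest.approx(base + c * (len(levels) - 1), abs=1e-9)

    def test_upper_bound_invariant(self):
        res = compute_auc([6] * 10)
        assert res.auc <= (6 - 1) * res.n_intervals + 1e-12

    def test_interior_gap_bridged_ends_trimmed(self):
        # [1, None, 3] bridges to [1, 2, 3]; leading None is trimmed
        assert compute_auc([1, None, 3]).auc == compute_auc([1, 2, 3]).auc
        assert compute_auc([None, 1, 3]).auc == compute_auc([1, 3]).auc

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_auc([3])
        with pytest.raises(InsufficientDataError):
            compute_auc([None, 3, None])


class TestHill:
    TRUE = dict(auc_max=400.0, e_m=380.0, ec50=3.0, k=2.0)
    CONCS = (250, 500, 1000, 2000, 4000, 8000, 16000, 32000)

    def test_closed_form_landmarks(self):
        # at x = ec50 the response is exactly auc_max - e_m/2
        assert hill_curve(np.array([3.0]), **self.TRUE)[0] == pytest.approx(400 - 190)
        assert hill_curve(np.array([1e-9]), **self.TRUE)[0] == pytest.approx(400, abs=1e-6)
        assert hill_curve(np.array([1e9]), **self.TRUE)[0] == pytest.approx(20, rel=1e-6)

    def test_noiseless_recovery(self):
        x = np.log2(self.CONCS)
        y = hill_curve(x, **self.TRUE)
        fit = fit_hill(dr_points(self.CONCS, y))
        for name, truth in self.TRUE.items():
            assert abs(getattr(fit, name) - truth) / truth < 1e-3
        assert fit.converged

    def test_anchored_fit_uses_three_free_parameters(self):
        x = np.log2(self.CONCS)
        y = hill_curve(x, **self.TRUE)
        fit = fit_hill(dr_points(self.CONCS, y), auc_max_anchor=400.0)
        assert fit.anchored and fit.auc_max == 400.0
        assert abs(fit.ec50 - 3.0) / 3.0 < 1e-3

    def test_underdetermined_rejected(self):
        pts = dr_points((250, 500, 1000), (100, 80, 60))
        with pytest.raises(UnderdeterminedError):
            fit_hill(pts)

    def test_flat_response_degenerate(self):
        pts = dr_points(self.CONCS, [200.0] * 8)
        with pytest.warns(DegenerateFitWarning):
            fit = fit_hill(pts)
        assert fit.e_m == pytest.approx(0.0, abs=1e-6)


class TestGompertz:
    def test_noiseless_recovery(self):
        t = np.arange(0, 2790, 30.0)
        y = gompertz_curve(t, 5.0, 0.02, 120.0, baseline=1.0)
        fit = fit_gompertz(list(y), minutes=t)
        assert abs(fit.A - 5.0) / 5.0 < 0.01
        assert abs(fit.mu_m - 0.02) / 0.02 < 0.01
        assert abs(fit.lam - 120.0) / 120.0 < 0.01
        assert fit.converged

    def test_lag_survives_level_quantization(self):
        t = np.arange(0, 2790, 30.0)
        y = gompertz_curve(t, 5.0, 0.02, 120.0, baseline=1.0)
        quantized = np.clip(np.round(y), 1, 6)
        fit = fit_gompertz(list(quantized), minutes=t)
        assert abs(fit.lam - 120.0) <= 30.0  # within one sampling interval

    def test_flat_curve_degenerate(self):
        with pytest.warns(DegenerateFitWarning):
            fit = fit_gompertz([1.0] * 10, minutes=np.arange(10) * 30.0)
        assert fit.A == 0.0 and not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_gompertz([1, 2, 3, 4], minutes=[0, 30, 60, 90])


def _session_from_levels(series, interval=30.0):
    n = len(next(iter(series.values())))
    return RunSession(
        config=RunConfig(interval_minutes=interval, n_timepoints=n),
        timepoints=[TimePoint(i, i * interval, f"frame_{i:03d}.png") for i in range(n)],
        series={k: list(v) for k, v in series.items()},
        n_levels=6,
    )


def _simulated_session(drug_effects, doses, n_timepoints=93, interval=30.0, seed=0):
    """Level series straight from simulated kinetics (no imaging)."""
    from platescan.density_model import default_levels, od_to_level_array
    from platescan.synth_data import DoseEffect, KineticsParams, simulate_od_trajectory

    levels = default_levels()
    times = np.arange(n_timepoints) * interval
    series = {}
    layout = {}
    rows = "ABCDEFGH"
    rng = np.random.default_rng(seed)
    for di, (drug, effect) in enumerate(drug_effects.items()):
        kp = KineticsParams(noise_sd=0.002, dose_effect=effect)
        for d, dose in enumerate(doses):
            for rep in range(3):
                label = f"{rows[3 * di + rep]}{d + 1}"
                od = simulate_od_trajectory(kp, dose, times, seed=rng)
                series[label] = od_to_level_array(od, levels).tolist()
                layout[label] = (drug, float(dose))
    # drug-free controls
    kp = KineticsParams(noise_sd=0.002)
    for rep in range(3):
        label = f"{rows[6]}{rep + 1}"
        od = simulate_od_trajectory(kp, 0.0, times, seed=rng)
        series[label] = od_to_level_array(od, levels).tolist()
        layout[label] = ("", 0.0)
    return _session_from_levels(series, interval), layout


class TestDoseResponse:
    DOSES = (250, 500, 1000, 2000, 4000, 8000, 16000, 32000)

    def test_auc_monotone_non_increasing_in_dose(self):
        from platescan.synth_data import DoseEffect

        session, layout = _simulated_session({"drugA": DoseEffect(hill_k=2.0)}, self.DOSES, seed=1)
        results = build_dose_response(session, layout, at_hours=46.0)
        res = results["drugA"]
        by_dose = {}
        for p in res.points:
            by_dose.setdefault(p.concentration, []).append(p.auc.auc)
        means = [np.mean(by_dose[c]) for c in sorted(by_dose)]
        assert all(a >= b - 2.0 for a, b in zip(means, means[1:]))  # small noise slack

    def test_hill_steepness_ordering_recovered(self):
        from platescan.synth_data import DoseEffect

        effects = {
            "shallow": DoseEffect(ec50_ugL=2000.0, hill_k=1.0),
            "steep": DoseEffect(ec50_ugL=2000.0, hill_k=4.0),
        }
        session, layout = _simulated_session(effects, self.DOSES, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateFitWarning)
            results = build_dose_response(session, layout, at_hours=46.0)
        assert results["steep"].fit is not None and results["shallow"].fit is not None
        assert results["steep"].fit.k > results["shallow"].fit.k

    def test_control_only_plate_reports_auc_max_without_fit(self):
        series = {"A1": [1, 2, 4, 6, 6], "A2": [1, 2, 5, 6, 6]}
        layout = {"A1": ("", 0.0), "A2": ("", 0.0)}
        session = _session_from_levels(series)
        results = build_dose_response(session, layout, at_hours=46.0)
        (res,) = results.values()
        assert res.fit is None
        expected = np.mean([compute_auc(v).auc for v in series.values()])
        assert res.control_auc.auc == pytest.approx(expected)

    def test_few_doses_returned_unfitted(self):
        series = {
            "A1": [1, 1, 1, 1, 1],
            "A2": [1, 2, 3, 3, 3],
            "A3": [1, 3, 5, 6, 6],
            "G1": [1, 4, 6, 6, 6],
        }
        layout = {
            "A1": ("drugX", 4000.0),
            "A2": ("drugX", 1000.0),
            "A3": ("drugX", 250.0),
            "G1": ("", 0.0),
        }
        session = _session_from_levels(series)
        results = build_dose_response(session, layout, at_hours=46.0)
        assert results["drugX"].fit is None
        assert len(results["drugX"].points) == 3

    def test_layout_and_report_io(self, tmp_path):
        from platescan.synth_data import DoseEffect

        layout_path = tmp_path / "layout.csv"
        layout_path.write_text(
            "well,antibiotic,concentration_ugL\nA1,drugA,250\nG1,,0\n"
        )
        layout = load_layout(layout_path)
        assert layout["A1"] == ("drugA", 250.0)
        assert layout["G1"] == ("", 0.0)

        session, lay = _simulated_session({"drugA": DoseEffect(hill_k=2.0)}, self.DOSES, seed=3)
        results = build_dose_response(session, lay, at_hours=46.0)
        save_fit_report(results, tmp_path / "fits.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "fits.csv")
        assert list(df.columns) == ["antibiotic", "auc_max", "e_m", "ec50", "k", "sse", "converged"]
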
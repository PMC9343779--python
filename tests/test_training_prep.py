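"""OD spreadsheets, tagging, grouping, flipped validation sets and evaluation."""

import numpy as np
import pandas as pd
import pytest

from platescan.density_model import od_to_level
from platescan.errors import EmptyEvaluationError, SpreadsheetFormatError
from platescan.plate_imaging import WELL_LABELS_96, load_well_image
from platescan.synth_data import render_well
from platescan.training_prep import (
    ODGrid,
    evaluate_model,
    export_evaluation,
    group_images_by_level,
    load_od_grid,
    make_flipped_validation_set,
    parse_od_from_filename,
    save_od_grid,
    tag_images_with_od,
)


def full_grid(missing=()):
    rng = np.random.default_rng(8)
    values = {lab: float(rng.uniform(0, 1.1)) for lab in WELL_LABELS_96}
    for lab in missing:
        values[lab] = None
    return ODGrid(values, plate_id="p0")


def wells_for(labels, od_by_label=None, seed=0):
    out = []
    for i, lab in enumerate(labels):
        od = od_by_label.get(lab, 0.1) if od_by_label else 0.1
        out.append(render_well(od, seed=(seed, i), label=lab, slice_index=i))
    return out


class TestODGrid:
    def test_labelled_csv_full_grid(self, tmp_path):
        path = save_od_grid(full_grid(), tmp_path / "od.csv")
        grid = load_od_grid(path)
        assert grid.n_present == 96
        assert set(grid.values) == set(WELL_LABELS_96)

    def test_xlsx_equals_csv_twin(self, tmp_path):
        g = full_grid()
        csv_grid = load_od_grid(save_od_grid(g, tmp_path / "od.csv"))
        xlsx_grid = load_od_grid(save_od_grid(g, tmp_path / "od.xlsx"))
        for lab in WELL_LABELS_96:
            assert csv_grid.get(lab) == pytest.approx(xlsx_grid.get(lab))

    def test_positional_block_accepted(self, tmp_path):
        block = np.random.default_rng(1).uniform(0, 1, (8, 12))
        p = tmp_path / "pos.csv"
        pd.DataFrame(block).to_csv(p, header=False, index=False)
        grid = load_od_grid(p)
        assert grid.get("A1") == pytest.approx(block[0, 0])
        assert grid.get("H12") == pytest.approx(block[7, 11])

    def test_missing_cell_recorded_as_missing(self, tmp_path):
        path = save_od_grid(full_grid(missing=("H12",)), tmp_path / "od.csv")
        grid = load_od_grid(path)
        assert grid.get("H12") is None
        assert grid.n_present == 95

    def test_non_numeric_cell_names_address(self, tmp_path):
        header = "," + ",".join(str(c) for c in range(1, 13))
        rows = [header]
        for r in "ABCDEFGH":
            cells = ["0.1"] * 12
            if r == "B":
                cells[2] = "oops"  # B3
            rows.append(r + "," + ",".join(cells))
        path = tmp_path / "od.csv"
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(SpreadsheetFormatError) as exc:
            load_od_grid(path)
        assert "B3" in str(exc.value)


class TestTagging:
    def test_full_grid_tags_96_files(self, tmp_path):
        grid = full_grid()
        written = tag_images_with_od(wells_for(WELL_LABELS_96), grid, tmp_path)
        assert len(written) == 96

    def test_filename_carries_well_and_od(self, tmp_path):
        grid = ODGrid({lab: (0.125 if lab == "B2" else 0.5) for lab in WELL_LABELS_96})
        written = tag_images_with_od(wells_for(["B2"]), grid, tmp_path)
        assert "B2_0.125" in written[0].name
        assert parse_od_from_filename(written[0]) == 0.125

    def test_missing_grid_cell_skipped(self, tmp_path):
        grid = full_grid(missing=("H12",))
        written = tag_images_with_od(wells_for(WELL_LABELS_96), grid, tmp_path)
        assert len(written) == 95
        assert not any("H12" in p.name for p in written)


class TestGrouping:
    def test_example_ods_land_in_printed_levels(self, tmp_path, levels):
        src = tmp_path / "tagged"
        src.mkdir()
        for od in (0.05, 0.10, 0.20):
            from PIL import Image

            Image.fromarray(np.zeros((5, 5), dtype=np.uint8)).save(src / f"p_A1_{od:.3f}.png")
        res = group_images_by_level(src, levels, tmp_path / "out")
        assert {k: v for k, v in res.counts.items() if v} == {1: 1, 2: 1, 3: 1}

    def test_empty_directory_all_zero(self, tmp_path, levels):
        src = tmp_path / "empty"
        src.mkdir()
        res = group_images_by_level(src, levels, tmp_path / "out")
        assert sum(res.counts.values()) == 0 and not res.rejects

    def test_file_conservation_with_rejects(self, tmp_path, levels):
        from PIL import Image

        src = tmp_path / "tagged"
        src.mkdir()
        n_tagged = 7
        for i in range(n_tagged):
            Image.fromarray(np.zeros((5, 5), dtype=np.uint8)).save(src / f"p_A1_{0.1 * (i + 1):.3f}.png")
        Image.fromarray(np.zeros((5, 5), dtype=np.uint8)).save(src / "untagged.png")
        res = group_images_by_level(src, levels, tmp_path / "out")
        assert sum(res.counts.values()) == n_tagged
        assert len(res.rejects) == 1
        assert res.total == n_tagged + 1
        assert (tmp_path / "out" / "rejects.txt").exists()

    def test_copy_is_default_move_optional(self, tmp_path, levels):
        from PIL import Image

        src = tmp_path / "tagged"
        src.mkdir()
        Image.fromarray(np.zeros((5, 5), dtype=np.uint8)).save(src / "p_A1_0.100.png")
        group_images_by_level(src, levels, tmp_path / "copy")
        assert (src / "p_A1_0.100.png").exists()
        group_images_by_level(src, levels, tmp_path / "moved", move=True)
        assert not (src / "p_A1_0.100.png").exists()


class TestFlippedValidationSet:
    def test_counts_structure_and_involution(self, training_tree, tmp_path):
        n_src = sum(1 for _ in training_tree.rglob("*.png"))
        flipped = tmp_path / "flipped"
        n = make_flipped_validation_set(training_tree, flipped)
        assert n == n_src
        src_dirs = sorted(d.name for d in training_tree.iterdir() if d.is_dir() and d.name.startswith("level_"))
        out_dirs = sorted(d.name for d in flipped.iterdir() if d.is_dir() and d.name.startswith("level_"))
        assert out_dirs == src_dirs
        # flipping the flipped set restores original pixels
        restored = tmp_path / "restored"
        make_flipped_validation_set(flipped, restored)
        some = sorted((training_tree / "level_3").glob("*.png"))[:3]
        for p in some:
            orig = load_well_image(p).pixels
            back = load_well_image(restored / "level_3" / p.name).pixels
            assert np.array_equal(orig, back)


class _StubEstimator:
    def __init__(self, fn):
        self.fn = fn

    def predict(self, X):
        return np.array([self.fn(row) for row in np.atleast_2d(X)])


def _stub_classifier(levels, fn):
    from platescan.density_model import WellClassifier

    return WellClassifier(kind="stub", levels=levels, estimator=_StubEstimator(fn))


class TestEvaluation:
    def _midpoint_pairs(self, levels, n_per_level=4, od_cap=1.2):
        pairs = []
        for k in range(1, levels.n_levels + 1):
            lo, up = levels.interval(k)
            up = min(up, od_cap)
            od = (lo + up) / 2
            for i in range(n_per_level):
                pairs.append((render_well(od, seed=(k, i), label="A1"), od))
        return pairs

    def test_perfect_predictor_identities(self, classifier, levels):
        """Interval-midpoint wells are classified perfectly: accuracy 1, R^2 1."""
        pairs = self._midpoint_pairs(levels)
        report = evaluate_model(classifier, pairs, levels)
        assert report.global_accuracy == 1.0
        assert report.r_squared == pytest.approx(1.0)
        assert np.trace(report.confusion) == report.n_pairs

    def test_constant_predictor_accuracy_and_r2(self, levels):
        clf = _stub_classifier(levels, lambda row: 1)
        pairs = self._midpoint_pairs(levels, n_per_level=3)
        report = evaluate_model(clf, pairs, levels)
        assert report.global_accuracy == pytest.approx(1 / 6)
        assert report.r_squared == 0.0

    def test_confusion_and_per_level_identities(self, classifier, levels):
        rng = np.random.default_rng(12)
        pairs = [
            (render_well(od, seed=(9, i), label="A1"), od)
            for i, od in enumerate(rng.uniform(0, 1.1, 120))
        ]
        report = evaluate_model(classifier, pairs, levels)
        # trace / total == global accuracy, exactly
        assert np.trace(report.confusion) / report.confusion.sum() == report.global_accuracy
        # confusion row sums equal measured-level counts
        for lvl, (acc, n) in report.per_level_accuracy.items():
            assert report.confusion[lvl - 1].sum() == n
        # count-weighted per-level accuracies average to the global accuracy
        weighted = sum(acc * n for acc, n in report.per_level_accuracy.values())
        assert weighted / report.n_pairs == pytest.approx(report.global_accuracy)

    def test_zero_pairs_rejected(self, classifier, levels):
        with pytest.raises(EmptyEvaluationError):
            evaluate_model(classifier, [], levels)

    def test_export_csvs(self, classifier, levels, tmp_path):
        report = evaluate_model(classifier, self._midpoint_pairs(levels, 2), levels)
        export_evaluation(report, tmp_path / "pairs.csv", tmp_path / "summary.csv")
        pairs = pd.read_csv(tmp_path / "pairs.csv")
        assert list(pairs.columns) == ["plate", "well", "measured_od", "measured_level", "assigned_level", "correct"]
        assert len(pairs) == report.n_pairs
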
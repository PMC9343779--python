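"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import pytest

from platescan.density_model import default_levels, train_classifier_from_tree
from platescan.plate_imaging import load_mask
from platescan.run_engine import RunConfig, run_offline
from platescan.synth_data import SyntheticPlateSpec, generate_training_set

TRAIN_SEED = 11
RUN_SEED = 5


@pytest.fixture(scope="session")
def levels():
    return default_levels()


@pytest.fixture(scope="session")
def training_tree(tmp_path_factory, levels):
    """Small level-sorted synthetic training set (default render noise)."""
    root = tmp_path_factory.mktemp("training_tree")
    generate_training_set(levels, 50, seed=TRAIN_SEED, out_dir=root)
    return root


@pytest.fixture(scope="session")
def classifier(training_tree, levels):
    return train_classifier_from_tree(training_tree, levels, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A 12-frame synthetic scan series with ground truth."""
    from platescan.synth_data import generate_run

    out = tmp_path_factory.mktemp("small_run")
    spec = SyntheticPlateSpec(seed=RUN_SEED, n_timepoints=12)
    return generate_run(spec, out)


@pytest.fixture(scope="session")
def small_session(small_run, classifier):
    mask = load_mask(small_run.mask_path)
    config = RunConfig(interval_minutes=30.0, n_timepoints=12)
    return run_offline(small_run.out_dir, config, mask=mask, clf=classifier)


@pytest.fixture(scope="session")
def full_run(tmp_path_factory, levels):
    """Full 46 h sample run at default noise: 93 frames, trained classifier.

    Returns (generated_run, session); shared by the end-to-end closure and
    dose-response recovery checks.
    """
    from platescan.synth_data import generate_run

    root = tmp_path_factory.mktemp("full_run")
    train_dir = root / "train"
    generate_training_set(levels, 200, seed=TRAIN_SEED, out_dir=train_dir)
    clf = train_classifier_from_tree(train_dir, levels, seed=TRAIN_SEED)
    spec = SyntheticPlateSpec(seed=RUN_SEED, n_timepoints=93)
    gen = generate_run(spec, root / "run")
    config = RunConfig(interval_minutes=30.0, n_timepoints=93)
    session = run_offline(gen.out_dir, config, mask=load_mask(gen.mask_path), clf=clf)
    return gen, session
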
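"""Shared fixtures: synthetic libraries and one session-scoped trained model."""

from dataclasses import replace

import numpy as np
import pytest

import ms2sim as m
from ms2sim.pipeline import _spectra_index, sample_eval_pairs


@pytest.fixture(scope="session")
def default_library():
    """The default synthetic library (seed 0): 300 molecules, 1200 spectra."""
    spectra, records = m.generate_library(m.SyntheticLibraryConfig(seed=0))
    return spectra, records


@pytest.fixture(scope="session")
def worked():
    return m.worked_example()


@pytest.fixture(scope="session")
def trained_setup(default_library):
    """Desk-scale Siamese model trained on the default library, with splits.

    Shared across the learning, evaluator and networking tests to keep the
    suite inside a CPU budget; all seeds fixed.
    """
    spectra, records = default_library
    split = m.split_library(spectra, seed=0)
    by_key = {r.inchikey14: r for r in records}
    tm_train = m.tanimoto_matrix([by_key[k] for k in sorted(split.train_molecules)])
    tm_test = m.tanimoto_matrix([by_key[k] for k in sorted(split.test_molecules)])
    selected = m.select_balanced_pairs(
        tm_train, m.SamplingConfig(pairs_per_bin=40, seed=1)
    )
    generator = m.PairGenerator(
        selected, _spectra_index(split.train, split.train_molecules), seed=2
    )
    cfg = m.ModelConfig.desk_scale()
    untrained = m.SiameseModel(cfg, seed=3)
    model = m.SiameseModel(cfg, seed=3)
    history = m.train(
        model, generator, val_pairs=None, cfg=replace(cfg.train, max_epochs=10)
    )
    test_pairs = sample_eval_pairs(split.test, tm_test, 300, seed=4)
    return {
        "split": split,
        "by_key": by_key,
        "tm_train": tm_train,
        "tm_test": tm_test,
        "model": model,
        "untrained": untrained,
        "history": history,
        "test_pairs": test_pairs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
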
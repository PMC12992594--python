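"""Embedding-quality labels, the MSE regressor, and quality filtering."""

import numpy as np
import pytest

import ms2sim as m
from ms2sim.chem import TanimotoMatrix
from ms2sim.evaluator import EvaluatorModel


class CosineOracleModel:
    """Duck-typed stand-in whose embedding cosines are fully controlled."""

    def __init__(self, embeddings, spectra):
        self._emb = {s.spectrum_id: e for s, e in zip(spectra, embeddings)}

    def embed_spectra(self, spectra):
        return np.stack([self._emb[s.spectrum_id] for s in spectra])


def make_spectra(n, keys):
    return [
        m.Spectrum(peaks=[[100.0 + i, 1.0]], precursor_mz=200.0,
                   ionmode="positive", inchikey=k + "-UHFFFAOYSA-N",
                   spectrum_id=f"s{i:03d}")
        for i, k in zip(range(n), keys)
    ]


class TestTrueMseLabels:
    def test_exact_model_gets_zero_labels(self, rng):
        # truth matrix defined as the cosine of the planted embeddings, so
        # the "model" predicts every pair perfectly
        n = 6
        emb = np.abs(rng.random((n, 8))) + 0.1
        unit = emb / np.linalg.norm(emb, axis=1, keepdims=True)
        keys = [f"MOL{i:011d}" for i in range(n)]
        spectra = make_spectra(n, keys)
        tm = TanimotoMatrix(inchikeys=keys, scores=unit @ unit.T)
        model = CosineOracleModel(emb, spectra)
        labels = m.true_mse_labels(model, spectra, tm, n_partners=3, seed=0)
        assert all(lab.true_mse == pytest.approx(0.0, abs=1e-12) for lab in labels)

    def test_matches_brute_force_recomputation(self, trained_setup):
        setup = trained_setup
        spectra = setup["split"].train[:5] + setup["split"].train[-6:]
        tm = setup["tm_train"]
        model = setup["model"]
        labels = m.true_mse_labels(model, spectra, tm, n_partners=10, seed=3)
        unit = model.embed_spectra(spectra)
        unit = unit / np.linalg.norm(unit, axis=1, keepdims=True)
        for i, lab in enumerate(labels):
            rng = np.random.default_rng([3, i])
            others = np.delete(np.arange(len(spectra)), i)
            partners = rng.choice(others, size=10, replace=False)
            errors = []
            for j in partners:
                pred = float(unit[i] @ unit[j])
                truth = tm.score(spectra[i].inchikey14, spectra[j].inchikey14)
                errors.append((pred - truth) ** 2)
            assert lab.true_mse == pytest.approx(np.mean(errors), rel=1e-12)

    def test_too_few_spectra_rejected(self, rng):
        keys = [f"MOL{i:011d}" for i in range(3)]
        spectra = make_spectra(3, keys)
        tm = TanimotoMatrix(inchikeys=keys, scores=np.eye(3) * 0.5 + 0.5)
        model = CosineOracleModel(rng.random((3, 4)) + 0.1, spectra)
        with pytest.raises(ValueError, match="n_partners"):
            m.true_mse_labels(model, spectra, tm, n_partners=5, seed=0)


class TestTrainEvaluator:
    def test_constant_labels_recovered(self, rng):
        # weight decay drives the exact constant solution (zero weights,
        # bias at softplus^-1(c)); full-batch training converges there
        emb = rng.normal(size=(80, 16))
        labels = [m.QualityLabel(f"s{i}", 0.2) for i in range(80)]
        ev = m.train_evaluator(
            emb,
            labels,
            m.EvaluatorConfig(max_epochs=500, learning_rate=1e-2,
                              weight_decay=0.3, batch_size=128, seed=0),
        )
        preds = ev.predict(emb)
        assert np.all(np.abs(preds - 0.2) < 0.02)  # within 10 % of 0.2

    def test_seeded_run_reproducible(self, rng):
        emb = rng.normal(size=(40, 16))
        labels = [m.QualityLabel(f"s{i}", float(abs(emb[i, 0]))) for i in range(40)]
        cfg = m.EvaluatorConfig(max_epochs=50, seed=1)
        a = m.train_evaluator(emb, labels, cfg).predict(emb)
        b = m.train_evaluator(emb, labels, cfg).predict(emb)
        np.testing.assert_array_equal(a, b)

    def test_recovers_planted_linear_signal_held_out(self, rng):
        # labels decodable from a linear projection of the embedding; the
        # projection uses uniform coefficients so it lies in the function
        # class of a (translation-invariant) conv + global-pool regressor
        emb = rng.normal(size=(300, 16))
        y = np.abs(emb @ np.ones(16)) * 0.02 + 0.05
        labels = [m.QualityLabel(f"s{i}", float(v)) for i, v in enumerate(y)]
        ev = m.train_evaluator(
            emb[:200], labels[:200], m.EvaluatorConfig(max_epochs=400, seed=2)
        )
        preds = ev.predict(emb[200:])
        residual = np.sum((preds - y[200:]) ** 2)
        baseline = np.sum((y[:200].mean() - y[200:]) ** 2)
        assert 1 - residual / baseline > 0.0

    def test_label_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            m.train_evaluator(rng.normal(size=(5, 8)),
                              [m.QualityLabel("a", 0.1)] * 4)


class TestPredictMse:
    def test_non_negative_on_random_embeddings(self, rng):
        ev = EvaluatorModel(16, m.EvaluatorConfig(seed=0))
        preds = m.predict_mse(ev, rng.normal(size=(1000, 16)))
        assert np.all(preds >= 0.0)

    def test_deterministic_and_scalar_for_single_embedding(self, rng):
        ev = EvaluatorModel(16, m.EvaluatorConfig(seed=0))
        e = rng.normal(size=16)
        assert m.predict_mse(ev, e) == m.predict_mse(ev, e)
        assert isinstance(m.predict_mse(ev, e), float)

    def test_dim_mismatch_rejected(self, rng):
        ev = EvaluatorModel(16, m.EvaluatorConfig(seed=0))
        with pytest.raises(ValueError, match="dim"):
            m.predict_mse(ev, rng.normal(size=(2, 8)))


class TestFilterByQuality:
    def test_retain_all_is_identity(self):
        spectra = make_spectra(5, [f"MOL{i:011d}" for i in range(5)])
        kept = m.filter_by_quality(spectra, [0.5, 0.1, 0.3, 0.2, 0.4], 1.0)
        assert kept == spectra

    def test_keeps_smallest_fraction(self):
        spectra = make_spectra(10, [f"MOL{i:011d}" for i in range(10)])
        predicted = [0.9, 0.1, 0.8, 0.05, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2]
        kept = m.filter_by_quality(spectra, predicted, 0.2)
        assert [s.spectrum_id for s in kept] == ["s001", "s003"]

    def test_ties_broken_by_spectrum_id(self):
        spectra = make_spectra(4, [f"MOL{i:011d}" for i in range(4)])
        kept = m.filter_by_quality(spectra, [0.1, 0.1, 0.1, 0.1], 0.5)
        assert [s.spectrum_id for s in kept] == ["s000", "s001"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            m.filter_by_quality([], [], 0.5)


def test_filtering_monotone_in_expectation(trained_setup):
    """Realized benchmark MSE is non-increasing in expectation as the
    retained fraction shrinks over {1.0, 0.8, 0.6, 0.4, 0.2}: the curve
    averaged over three label/evaluator seeds shows at most one inversion."""
    from ms2sim.pipeline import _benchmark_spectra

    setup = trained_setup
    model, split = setup["model"], setup["split"]
    tm_train, tm_test = setup["tm_train"], setup["tm_test"]
    emb_train = model.embed_spectra(split.train)
    test = [s for s in split.test if s.inchikey14 in tm_test.index]
    emb_test = model.embed_spectra(test)
    curves = []
    for label_seed, ev_seed in ((7, 8), (17, 18), (27, 28)):
        labels = m.true_mse_labels(
            model, split.train, tm_train, n_partners=500, seed=label_seed
        )
        ev = m.train_evaluator(emb_train, labels, m.EvaluatorConfig(seed=ev_seed))
        predicted = list(m.predict_mse(ev, emb_test))
        curves.append(
            [
                _benchmark_spectra(
                    model, m.filter_by_quality(test, predicted, f), tm_test
                ).final_loss
                for f in (1.0, 0.8, 0.6, 0.4, 0.2)
            ]
        )
    mean_curve = np.mean(curves, axis=0)
    inversions = sum(b > a + 1e-12 for a, b in zip(mean_curve, mean_curve[1:]))
    assert inversions <= 1
    assert mean_curve[-1] < mean_curve[0]


def test_evaluator_save_load_round_trip(tmp_path, rng):
    from ms2sim.evaluator import load_evaluator

    emb = rng.normal(size=(30, 16))
    labels = [m.QualityLabel(f"s{i}", 0.1) for i in range(30)]
    ev = m.train_evaluator(emb, labels, m.EvaluatorConfig(max_epochs=20, seed=0))
    ev.save(tmp_path / "ev")
    back = load_evaluator(tmp_path / "ev")
    np.testing.assert_array_equal(ev.predict(emb), back.predict(emb))
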
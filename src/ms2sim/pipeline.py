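"""End-to-end orchestration: clean -> split -> sample pairs -> train -> evaluate.

A single :class:`PipelineSettings` document (serializable to JSON) carries
every stage's configuration plus one global seed, which fans out to
per-stage seeds through a fixed stage-name hash so stages are individually
reproducible.  Training produces a self-describing artifact directory::

    out_dir/
      model/        weights.npz + settings.json
      evaluator/    weights.npz + settings.json
      reports/      split_manifest.json, sampling_report.json, benchmark.json
      run.log

Inference loads such a directory, embeds query spectra, predicts the
similarity matrix and per-spectrum quality, and writes the molecular
network (GraphML) plus an optional 2-D embedding map.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import benchmark as bench
from .chem import MoleculeRecord, TanimotoMatrix, load_fingerprints, records_from_spectra, save_fingerprints, tanimoto_matrix
from .evaluator import (
    EvaluatorConfig,
    filter_by_quality,
    load_evaluator,
    predict_mse,
    train_evaluator,
    true_mse_labels,
)
from .networking import NetworkConfig, build_network, project_embeddings_2d, write_graphml
from .pair_sampling import PairGenerator, SamplingConfig, SelectedPairs, sampling_report, select_balanced_pairs
from .siamese import ModelConfig, SiameseModel, load_model, predict_matrix, train
from .spectra_io import Spectrum, clean_spectra, read_mgf, split_library, write_split_manifest

__all__ = ["PipelineSettings", "stage_seed", "run_training_pipeline", "run_inference"]

logger = logging.getLogger("ms2sim")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed and the stage name."""
    return (zlib.crc32(stage.encode()) ^ global_seed) % (2**31)


@dataclass(frozen=True)
class PipelineSettings:
    """Every stage's configuration in one JSON-serializable document."""

    min_fragments: int = 4
    mz_range: tuple[float, float] = (10.0, 1000.0)
    split_fraction: float = 1 / 20
    model: ModelConfig = field(default_factory=ModelConfig)
    sampling: SamplingConfig = SamplingConfig()
    evaluator: EvaluatorConfig = EvaluatorConfig()
    network: NetworkConfig = NetworkConfig()
    n_partners: int = 999
    n_val_pairs: int = 200
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "min_fragments": self.min_fragments,
            "mz_range": list(self.mz_range),
            "split_fraction": self.split_fraction,
            "model": self.model.to_dict(),
            "sampling": self.sampling.to_dict(),
            "evaluator": self.evaluator.to_dict(),
            "network": self.network.to_dict(),
            "n_partners": self.n_partners,
            "n_val_pairs": self.n_val_pairs,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineSettings":
        return cls(
            min_fragments=data["min_fragments"],
            mz_range=tuple(data["mz_range"]),
            split_fraction=data["split_fraction"],
            model=ModelConfig.from_dict(data["model"]),
            sampling=SamplingConfig(**data["sampling"]),
            evaluator=EvaluatorConfig.from_dict(data["evaluator"]),
            network=NetworkConfig(**data["network"]),
            n_partners=data["n_partners"],
            n_val_pairs=data["n_val_pairs"],
            seed=data["seed"],
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineSettings":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _spectra_index(
    spectra: Sequence[Spectrum], molecules: set[str]
) -> dict[str, list[Spectrum]]:
    index: dict[str, list[Spectrum]] = {}
    for spectrum in spectra:
        key = spectrum.inchikey14
        if key in molecules:
            index.setdefault(key, []).append(spectrum)
    return index


def sample_eval_pairs(
    spectra: Sequence[Spectrum], tm: TanimotoMatrix, n_pairs: int, seed: int
) -> list[tuple[Spectrum, Spectrum, float]]:
    """Fixed random spectrum pairs with their true Tanimoto, for validation."""
    eligible = [s for s in spectra if s.inchikey14 in tm.index]
    if len(eligible) < 2:
        raise ValueError("need at least two spectra with known molecules")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(eligible), size=2, replace=False)
        a, b = eligible[int(i)], eligible[int(j)]
        pairs.append((a, b, tm.score(a.inchikey14, b.inchikey14)))
    return pairs


def _benchmark_spectra(
    model: SiameseModel, spectra: Sequence[Spectrum], tm: TanimotoMatrix
) -> bench.BenchmarkResult:
    """All-vs-all spectrum-pair benchmark with molecule-pair averaging."""
    eligible = [s for s in spectra if s.inchikey14 in tm.index]
    sim = predict_matrix(model, eligible, eligible)
    iu, ju = np.triu_indices(len(eligible), k=1)
    preds = sim[iu, ju]
    truths = np.array(
        [tm.score(eligible[i].inchikey14, eligible[j].inchikey14)
         for i, j in zip(iu, ju)]
    )
    molecule_ids = [
        (eligible[i].inchikey14, eligible[j].inchikey14) for i, j in zip(iu, ju)
    ]
    pair_means = bench.molecule_pair_losses(preds, truths, molecule_ids)
    return bench.binned_mse(
        pair_means["mean_loss"].to_numpy(), pair_means["tanimoto"].to_numpy()
    )


def run_training_pipeline(
    library_path: str | Path,
    settings: PipelineSettings,
    out_dir: str | Path,
    records: Sequence[MoleculeRecord] | None = None,
    fingerprints_dir: str | Path | None = None,
) -> Path:
    """Execute the full training pipeline and write the artifact directory.

    ``records`` (or a persisted fingerprint table in ``fingerprints_dir``)
    supplies molecule fingerprints directly; otherwise they are computed
    from the spectra's SMILES annotations.
    """
    out_dir = Path(out_dir)
    (out_dir / "reports").mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_training(library_path, settings, out_dir, records, fingerprints_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_training(library_path, settings, out_dir, records, fingerprints_dir) -> Path:
    stage = "read"
    try:
        spectra = read_mgf(library_path)
        logger.info("read: %d spectra from %s", len(spectra), library_path)

        stage = "clean"
        cleaned = clean_spectra(
            spectra, settings.min_fragments, settings.mz_range, for_training=True
        )
        logger.info(
            "clean: %d in = %d kept + %d filtered",
            len(spectra), len(cleaned), len(spectra) - len(cleaned),
        )

        stage = "split"
        split = split_library(
            cleaned, settings.split_fraction, stage_seed(settings.seed, "split")
        )
        write_split_manifest(split, out_dir / "reports" / "split_manifest.json")
        logger.info(
            "split: %d train / %d validation / %d test spectra",
            len(split.train), len(split.validation), len(split.test),
        )

        stage = "fingerprints"
        if records is None:
            if fingerprints_dir is not None:
                records = load_fingerprints(fingerprints_dir)
            else:
                records = records_from_spectra(cleaned)
        by_key = {r.inchikey14: r for r in records}
        logger.info("fingerprints: %d molecule records", len(records))

        stage = "pair_selection"
        train_records = [by_key[k] for k in sorted(split.train_molecules) if k in by_key]
        tm_train = tanimoto_matrix(train_records)
        sampling = replace(
            settings.sampling, seed=stage_seed(settings.seed, "pair_selection")
        )
        selected = select_balanced_pairs(tm_train, sampling)
        report = sampling_report(selected)
        (out_dir / "reports" / "sampling_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        logger.info(
            "pair_selection: %d pairs, disparity %.2f%%",
            report["n_pairs"], report["max_disparity_percent"],
        )

        stage = "train"
        generator = PairGenerator(
            selected,
            _spectra_index(split.train, split.train_molecules),
            seed=stage_seed(settings.seed, "generator"),
        )
        val_records = [by_key[k] for k in sorted(split.validation_molecules) if k in by_key]
        val_pairs = None
        if len(val_records) >= 2:
            tm_val = tanimoto_matrix(val_records)
            val_pairs = sample_eval_pairs(
                split.validation, tm_val, settings.n_val_pairs,
                stage_seed(settings.seed, "val_pairs"),
            )
        model = SiameseModel(settings.model, seed=stage_seed(settings.seed, "init"))
        history = train(model, generator, val_pairs)
        model.save(out_dir / "model")
        (out_dir / "reports" / "history.json").write_text(
            json.dumps(history, indent=2)
        )
        logger.info(
            "train: %d epochs, final train loss %.4f",
            len(history["train_loss"]),
            history["train_loss"][-1] if history["train_loss"] else float("nan"),
        )

        stage = "evaluator"
        n_partners = min(settings.n_partners, len(split.train) - 1)
        labels = true_mse_labels(
            model, split.train, tm_train, n_partners,
            seed=stage_seed(settings.seed, "labels"),
        )
        embeddings = model.embed_spectra(split.train)
        evaluator = train_evaluator(embeddings, labels, settings.evaluator)
        evaluator.save(out_dir / "evaluator")
        logger.info("evaluator: trained on %d labeled spectra", len(labels))

        stage = "benchmark"
        test_records = [by_key[k] for k in sorted(split.test_molecules) if k in by_key]
        if len(test_records) >= 2:
            tm_test = tanimoto_matrix(test_records)
            result = _benchmark_spectra(model, split.test, tm_test)
            (out_dir / "reports" / "benchmark.json").write_text(
                json.dumps(result.to_dict(), indent=2, sort_keys=True)
            )
            logger.info("benchmark: final loss %.4f", result.final_loss)
        return out_dir
    except Exception:
        logger.exception("pipeline aborted in stage %r", stage)
        raise


def run_inference(
    model_dir: str | Path,
    query_mgf: str | Path,
    cfg: NetworkConfig = NetworkConfig(),
    out_dir: str | Path = "inference",
    seed: int = 0,
    umap_neighbors: int = 50,
) -> dict:
    """Embed queries, predict similarities, write network, map and quality TSV."""
    model_dir = Path(model_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = load_model(model_dir / "model")
    queries = read_mgf(query_mgf)
    if not queries:
        raise ValueError(f"no spectra in {query_mgf}")
    sim = predict_matrix(model, queries, queries)
    nodes = [
        {
            "spectrum_id": s.spectrum_id,
            "ionmode": s.ionmode,
            "precursor_mz": s.precursor_mz,
        }
        for s in queries
    ]
    net = build_network(sim, nodes, cfg)
    write_graphml(net, out_dir / "network.graphml")
    np.savetxt(out_dir / "similarity.tsv", sim, delimiter="\t", fmt="%.6f")

    result = {"n_queries": len(queries), "n_edges": len(net.edges), "similarity": sim}
    evaluator_dir = model_dir / "evaluator"
    embeddings = model.embed_spectra(queries)
    if evaluator_dir.exists():
        evaluator = load_evaluator(evaluator_dir)
        quality = predict_mse(evaluator, embeddings)
        with (out_dir / "quality.tsv").open("w") as handle:
            handle.write("spectrum_id\tpredicted_mse\n")
            for spectrum, q in zip(queries, np.atleast_1d(quality)):
                handle.write(f"{spectrum.spectrum_id}\t{q:.6f}\n")
        result["predicted_mse"] = np.atleast_1d(quality)
    if len(queries) >= umap_neighbors + 1:
        coords = project_embeddings_2d(embeddings, umap_neighbors, seed=seed)
        with (out_dir / "embedding_map.tsv").open("w") as handle:
            handle.write("spectrum_id\tx\ty\tionmode\n")
            for spectrum, (x, y) in zip(queries, coords):
                handle.write(f"{spectrum.spectrum_id}\t{x:.4f}\t{y:.4f}\t{spectrum.ionmode}\n")
        result["coordinates"] = coords
    return result
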
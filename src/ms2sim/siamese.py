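"""The Siamese spectral-embedding model: architecture, prediction, training.

Two weight-sharing dense arms map featurized spectra (metadata channel plus
binned fragment channel) to fixed-length embeddings; the cosine similarity
between two embeddings is the predicted chemical (Tanimoto) similarity.
Training minimizes the mean squared error between predicted cosine and true
Tanimoto over balanced molecule-pair batches, with augmentation applied to
the fragment channel only.  The reference architecture is a single hidden
layer of 10,000 units and a 500-dimensional embedding with a Tanh output
activation and no dropout or batch normalization; a small "desk-scale"
profile (512 hidden, 64-dim embedding) is provided for CPU-sized runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .nn import Adam, relu, relu_grad
from .spectra_io import Spectrum
from .tensorize import (
    AugmentConfig,
    BinningScheme,
    MetadataSpec,
    augment,
    bin_peaks,
    default_metadata_spec,
    encode_metadata,
)

__all__ = ["TrainConfig", "ModelConfig", "SiameseModel", "train",
           "predict_similarity", "predict_matrix", "load_model"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ModelConfig:
    """Featurizer plus architecture plus training settings; self-describing."""

    binning: BinningScheme = BinningScheme()
    metadata: MetadataSpec = field(default_factory=default_metadata_spec)
    hidden_layers: tuple[int, ...] = (10000,)
    embedding_dim: int = 500
    final_activation: str = "tanh"
    augment: AugmentConfig = AugmentConfig()
    train: TrainConfig = TrainConfig()

    def __post_init__(self) -> None:
        if not self.hidden_layers:
            raise ValueError("at least one hidden layer is required")
        if any(w < 1 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be >= 1")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.final_activation not in ("tanh", "relu"):
            raise ValueError("final_activation must be 'tanh' or 'relu'")

    @property
    def input_dim(self) -> int:
        return self.metadata.width + self.binning.n_bins

    @property
    def param_count(self) -> int:
        """Total weight + bias count of the dense tower (analytic)."""
        dims = [self.input_dim, *self.hidden_layers, self.embedding_dim]
        return sum(a * b + b for a, b in zip(dims[:-1], dims[1:]))

    @classmethod
    def desk_scale(cls, **overrides) -> "ModelConfig":
        """Small CPU-friendly profile: 512 hidden units, 64-dim embedding."""
        base = cls(
            hidden_layers=(512,),
            embedding_dim=64,
            train=TrainConfig(learning_rate=1e-3),
        )
        return replace(base, **overrides) if overrides else base

    def to_dict(self) -> dict:
        return {
            "binning": self.binning.to_dict(),
            "metadata": self.metadata.to_dict(),
            "hidden_layers": list(self.hidden_layers),
            "embedding_dim": self.embedding_dim,
            "final_activation": self.final_activation,
            "augment": self.augment.to_dict(),
            "train": self.train.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        return cls(
            binning=BinningScheme(**data["binning"]),
            metadata=MetadataSpec.from_dict(data["metadata"]),
            hidden_layers=tuple(data["hidden_layers"]),
            embedding_dim=data["embedding_dim"],
            final_activation=data["final_activation"],
            augment=AugmentConfig(**data["augment"]),
            train=TrainConfig(**data["train"]),
        )


class SiameseModel:
    """Weight-sharing dense tower mapping feature vectors to embeddings."""

    def __init__(self, cfg: ModelConfig, seed: int | None = None) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.train.seed if seed is None else seed)
        dims = [cfg.input_dim, *cfg.hidden_layers, cfg.embedding_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for n_in, n_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (n_in + n_out))
            self.weights.append(rng.uniform(-limit, limit, size=(n_in, n_out)))
            self.biases.append(np.zeros(n_out))

    # ---------------------------------------------------------------- featurize
    def featurize(self, spectrum: Spectrum) -> np.ndarray:
        return np.concatenate(
            [
                encode_metadata(spectrum, self.cfg.metadata),
                bin_peaks(spectrum, self.cfg.binning),
            ]
        )

    # ------------------------------------------------------------------ forward
    def _final_act(self, pre: np.ndarray) -> np.ndarray:
        return np.tanh(pre) if self.cfg.final_activation == "tanh" else relu(pre)

    def _forward(self, X: np.ndarray):
        """Forward pass returning (embeddings, cache) for backprop."""
        cache = []
        h = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            pre = h @ W + b
            post = self._final_act(pre) if i == last else relu(pre)
            cache.append((h, pre, post))
            h = post
        return h, cache

    def _backward(self, cache, d_emb: np.ndarray, grad_W, grad_b) -> None:
        """Accumulate parameter gradients for one arm into grad_W/grad_b."""
        d = d_emb
        last = len(self.weights) - 1
        for i in reversed(range(len(self.weights))):
            h, pre, post = cache[i]
            if i == last and self.cfg.final_activation == "tanh":
                d = d * (1.0 - post**2)
            else:
                d = d * relu_grad(pre)
            grad_W[i] += h.T @ d
            grad_b[i] += d.sum(axis=0)
            d = d @ self.weights[i].T

    def embed(self, features: np.ndarray) -> np.ndarray:
        """Embeddings for a (batch, input_dim) feature matrix; deterministic."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.cfg.input_dim:
            raise ValueError(
                f"feature length {features.shape[1]} != model input_dim "
                f"{self.cfg.input_dim}"
            )
        out, _ = self._forward(features)
        return out

    def embed_spectra(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        if not spectra:
            return np.zeros((0, self.cfg.embedding_dim))
        return self.embed(np.stack([self.featurize(s) for s in spectra]))

    @property
    def n_params(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    # -------------------------------------------------------------- persistence
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(directory / "weights.npz", **arrays)
        (directory / "settings.json").write_text(json.dumps(self.cfg.to_dict(), indent=2))


def load_model(directory: str | Path) -> SiameseModel:
    directory = Path(directory)
    cfg = ModelConfig.from_dict(json.loads((directory / "settings.json").read_text()))
    model = SiameseModel(cfg)
    data = np.load(directory / "weights.npz")
    for i in range(len(model.weights)):
        model.weights[i] = data[f"W{i}"]
        model.biases[i] = data[f"b{i}"]
    return model


def _cosine_rows(ea: np.ndarray, eb: np.ndarray) -> tuple[np.ndarray, ...]:
    na = np.linalg.norm(ea, axis=1)
    nb = np.linalg.norm(eb, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-norm embedding: cosine similarity is undefined")
    cos = (ea * eb).sum(axis=1) / (na * nb)
    return cos, na, nb


def predict_similarity(model: SiameseModel, spec_a: Spectrum, spec_b: Spectrum) -> float:
    """Cosine similarity of the two spectra's embeddings, in [-1, 1]."""
    emb = model.embed_spectra([spec_a, spec_b])
    cos, _, _ = _cosine_rows(emb[:1], emb[1:])
    return float(cos[0])


def predict_matrix(
    model: SiameseModel,
    queries: Sequence[Spectrum],
    references: Sequence[Spectrum],
) -> np.ndarray:
    """Score matrix (i, j) = cosine(embed(queries[i]), embed(references[j]))."""
    if not queries or not references:
        return np.zeros((len(queries), len(references)))
    eq = model.embed_spectra(queries)
    er = model.embed_spectra(references)
    nq = np.linalg.norm(eq, axis=1, keepdims=True)
    nr = np.linalg.norm(er, axis=1, keepdims=True)
    if np.any(nq == 0) or np.any(nr == 0):
        raise ValueError("zero-norm embedding: cosine similarity is undefined")
    return (eq / nq) @ (er / nr).T


def _validation_loss(model: SiameseModel, val_pairs, feature_cache: dict) -> float:
    """Molecule-pair-averaged, Tanimoto-binned MSE on a fixed pair list."""
    from .benchmark import binned_mse, molecule_pair_losses

    feats_a, feats_b, truths, mol_a, mol_b = [], [], [], [], []
    for spec_a, spec_b, truth in val_pairs:
        for spec in (spec_a, spec_b):
            if spec.spectrum_id not in feature_cache:
                feature_cache[spec.spectrum_id] = model.featurize(spec)
        feats_a.append(feature_cache[spec_a.spectrum_id])
        feats_b.append(feature_cache[spec_b.spectrum_id])
        truths.append(truth)
        mol_a.append(spec_a.inchikey14 or spec_a.spectrum_id)
        mol_b.append(spec_b.inchikey14 or spec_b.spectrum_id)
    ea, _ = model._forward(np.stack(feats_a))
    eb, _ = model._forward(np.stack(feats_b))
    cos, _, _ = _cosine_rows(ea, eb)
    pair_means = molecule_pair_losses(cos, np.array(truths), list(zip(mol_a, mol_b)))
    result = binned_mse(
        pair_means["mean_loss"].to_numpy(), pair_means["tanimoto"].to_numpy()
    )
    return result.final_loss


def train(
    model: SiameseModel,
    generator,
    val_pairs: list | None = None,
    cfg: TrainConfig | None = None,
) -> dict:
    """Train the Siamese tower on the generator's spectrum-pair stream.

    Per batch the loss is mean((cosine(e_a, e_b) - tanimoto)^2); gradients
    from both arms flow into the shared weights.  Augmentation perturbs the
    fragment channel of every training feature vector.  Early stopping
    tracks the validation loss (molecule-pair-averaged binned MSE on
    ``val_pairs``) with the configured patience and restores the best
    weights.  Returns a history dict with per-epoch train/val losses.
    """
    cfg = cfg or model.cfg.train
    if len(generator) == 0:
        raise ValueError("pair generator yields no training examples")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.weights + model.biases, lr=cfg.learning_rate)
    meta_width = model.cfg.metadata.width
    binned_cache: dict[str, np.ndarray] = {}
    meta_cache: dict[str, np.ndarray] = {}
    val_cache: dict[str, np.ndarray] = {}

    def features_for(spec: Spectrum) -> np.ndarray:
        if spec.spectrum_id not in binned_cache:
            binned_cache[spec.spectrum_id] = bin_peaks(spec, model.cfg.binning)
            meta_cache[spec.spectrum_id] = encode_metadata(spec, model.cfg.metadata)
        fragments = augment(binned_cache[spec.spectrum_id], model.cfg.augment, rng)
        return np.concatenate([meta_cache[spec.spectrum_id], fragments])

    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = None
    bad_epochs = 0
    for epoch in range(cfg.max_epochs):
        examples = list(generator.epoch())
        epoch_losses = []
        for start in range(0, len(examples), cfg.batch_size):
            batch = examples[start : start + cfg.batch_size]
            A = np.stack([features_for(a) for a, _, _ in batch])
            B = np.stack([features_for(b) for _, b, _ in batch])
            t = np.array([s for _, _, s in batch])
            ea, cache_a = model._forward(A)
            eb, cache_b = model._forward(B)
            cos, na, nb = _cosine_rows(ea, eb)
            err = cos - t
            epoch_losses.append(float(np.mean(err**2)))
            dcos = (2.0 / len(batch)) * err
            d_ea = dcos[:, None] * (
                eb / (na * nb)[:, None] - (cos / na**2)[:, None] * ea
            )
            d_eb = dcos[:, None] * (
                ea / (na * nb)[:, None] - (cos / nb**2)[:, None] * eb
            )
            grad_W = [np.zeros_like(W) for W in model.weights]
            grad_b = [np.zeros_like(b) for b in model.biases]
            model._backward(cache_a, d_ea, grad_W, grad_b)
            model._backward(cache_b, d_eb, grad_W, grad_b)
            opt.step(grad_W + grad_b)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_pairs:
            val_loss = _validation_loss(model, val_pairs, val_cache)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_weights = (
                    [W.copy() for W in model.weights],
                    [b.copy() for b in model.biases],
                )
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > cfg.patience:
                    break
    if best_weights is not None:
        model.weights, model.biases = best_weights
    return history
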
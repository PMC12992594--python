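"""Embedding-quality estimation: predicting a spectrum's similarity MSE.

Some spectra — poorly fragmented, chimeric, or unlike anything in the
training library — produce embeddings whose similarity predictions are
systematically wrong.  Each training spectrum is labeled with its *true*
MSE: the mean squared error between predicted and true Tanimoto over a
random sample of partner spectra (999 by default).  A small 1-D
convolutional regressor in the Inception style (parallel kernel sizes whose
feature maps are concatenated, then globally pooled) is trained to predict
that MSE directly from the embedding, and a softplus output map keeps the
prediction non-negative.  Filtering out spectra with high predicted MSE
raises the realized accuracy of the remaining predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import TanimotoMatrix
from .nn import Adam, Conv1dSame, Dense, relu, relu_grad, softplus, softplus_grad
from .siamese import SiameseModel
from .spectra_io import Spectrum

__all__ = [
    "QualityLabel",
    "EvaluatorConfig",
    "EvaluatorModel",
    "true_mse_labels",
    "train_evaluator",
    "predict_mse",
    "filter_by_quality",
    "load_evaluator",
]


@dataclass(frozen=True)
class QualityLabel:
    """True similarity-prediction MSE of one spectrum."""

    spectrum_id: str
    true_mse: float

    def __post_init__(self) -> None:
        if self.true_mse < 0:
            raise ValueError("true_mse must be >= 0")


@dataclass(frozen=True)
class EvaluatorConfig:
    """Desk-scale Inception-style regressor settings."""

    kernel_sizes: tuple[int, ...] = (3, 9, 19)
    filters: int = 16
    learning_rate: float = 3e-3
    weight_decay: float = 1e-2
    max_epochs: int = 300
    batch_size: int = 64
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "kernel_sizes": list(self.kernel_sizes),
            "filters": self.filters,
            "learning_rate": self.learning_rate,
            "weight_decay": self.weight_decay,
            "max_epochs": self.max_epochs,
            "batch_size": self.batch_size,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "EvaluatorConfig":
        data = dict(data)
        data["kernel_sizes"] = tuple(data["kernel_sizes"])
        return cls(**data)


class EvaluatorModel:
    """Parallel 1-D convolutions over the embedding -> pooled dense head."""

    def __init__(self, embedding_dim: int, cfg: EvaluatorConfig) -> None:
        self.cfg = cfg
        self.embedding_dim = embedding_dim
        rng = np.random.default_rng(cfg.seed)
        self.convs = [Conv1dSame(k, cfg.filters, rng) for k in cfg.kernel_sizes]
        self.head = Dense(len(cfg.kernel_sizes) * cfg.filters, 1, rng)

    def _forward(self, X: np.ndarray):
        maps = []
        pres = []
        for conv in self.convs:
            pre = conv.forward(X)  # (batch, length, filters)
            pres.append(pre)
            maps.append(relu(pre))
        concat = np.concatenate(maps, axis=2)  # (batch, length, total_filters)
        pooled = concat.mean(axis=1)  # global average pool
        head_pre = self.head.forward(pooled).ravel()
        out = softplus(head_pre)
        return out, (pres, head_pre, X.shape[1])

    def _backward(self, d_out: np.ndarray, cache) -> list[np.ndarray]:
        pres, head_pre, length = cache
        d_head_pre = (d_out * softplus_grad(head_pre))[:, None]
        d_pooled = self.head.backward(d_head_pre)
        d_concat = np.repeat(d_pooled[:, None, :] / length, length, axis=1)
        grads: list[np.ndarray] = []
        offset = 0
        for conv, pre in zip(self.convs, pres):
            f = conv.W.shape[1]
            d_map = d_concat[:, :, offset : offset + f] * relu_grad(pre)
            conv.backward(d_map)
            grads.extend(conv.grads)
            offset += f
        grads.extend(self.head.grads)
        return grads

    @property
    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for conv in self.convs:
            out.extend(conv.params)
        out.extend(self.head.params)
        return out

    def predict(self, embeddings: np.ndarray) -> np.ndarray:
        embeddings = np.atleast_2d(np.asarray(embeddings, dtype=float))
        if embeddings.shape[1] != self.embedding_dim:
            raise ValueError(
                f"embedding dim {embeddings.shape[1]} != evaluator dim "
                f"{self.embedding_dim}"
            )
        out, _ = self._forward(embeddings)
        return out

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, conv in enumerate(self.convs):
            arrays[f"convW{i}"], arrays[f"convb{i}"] = conv.W, conv.b
        arrays["headW"], arrays["headb"] = self.head.W, self.head.b
        np.savez(directory / "weights.npz", **arrays)
        settings = {"embedding_dim": self.embedding_dim, "config": self.cfg.to_dict()}
        (directory / "settings.json").write_text(json.dumps(settings, indent=2))


def load_evaluator(directory: str | Path) -> EvaluatorModel:
    directory = Path(directory)
    settings = json.loads((directory / "settings.json").read_text())
    model = EvaluatorModel(
        settings["embedding_dim"], EvaluatorConfig.from_dict(settings["config"])
    )
    data = np.load(directory / "weights.npz")
    for i, conv in enumerate(model.convs):
        conv.W, conv.b = data[f"convW{i}"], data[f"convb{i}"]
    model.head.W, model.head.b = data["headW"], data["headb"]
    return model


def true_mse_labels(
    model: SiameseModel,
    spectra: Sequence[Spectrum],
    tm: TanimotoMatrix,
    n_partners: int = 999,
    seed: int = 0,
) -> list[QualityLabel]:
    """Label each spectrum with its realized similarity-prediction MSE.

    For spectrum *i*, ``n_partners`` distinct partner spectra are drawn
    without replacement (fresh seeded stream per spectrum index), the cosine
    similarity of the embeddings is compared against the true Tanimoto of
    the underlying molecules, and the mean squared error is recorded.
    """
    n = len(spectra)
    if n_partners > n - 1:
        raise ValueError(
            f"n_partners={n_partners} requires at least {n_partners + 1} spectra, "
            f"got {n}"
        )
    embeddings = model.embed_spectra(spectra)
    norms = np.linalg.norm(embeddings, axis=1, keepdims=True)
    unit = embeddings / norms
    mol_idx = np.array([tm.index[s.inchikey14] for s in spectra])
    labels = []
    for i, spectrum in enumerate(spectra):
        rng = np.random.default_rng([seed, i])
        others = np.delete(np.arange(n), i)
        partners = rng.choice(others, size=n_partners, replace=False)
        preds = unit[partners] @ unit[i]
        truths = tm.scores[mol_idx[i], mol_idx[partners]]
        labels.append(
            QualityLabel(spectrum.spectrum_id, float(np.mean((preds - truths) ** 2)))
        )
    return labels


def train_evaluator(
    embeddings: np.ndarray,
    labels: Sequence[QualityLabel],
    cfg: EvaluatorConfig = EvaluatorConfig(),
) -> EvaluatorModel:
    """Fit the quality regressor to (embedding, true MSE) pairs with Adam."""
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if embeddings.shape[0] != len(labels):
        raise ValueError(
            f"{embeddings.shape[0]} embeddings but {len(labels)} labels"
        )
    y = np.array([lab.true_mse for lab in labels])
    model = EvaluatorModel(embeddings.shape[1], cfg)
    opt = Adam(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    n = embeddings.shape[0]
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            out, cache = model._forward(embeddings[idx])
            d_out = 2.0 * (out - y[idx]) / idx.size
            grads = model._backward(d_out, cache)
            opt.step(grads)
    return model


def predict_mse(evaluator: EvaluatorModel, embedding: np.ndarray) -> float | np.ndarray:
    """Predicted similarity MSE (>= 0) for one embedding or a batch."""
    embedding = np.asarray(embedding, dtype=float)
    single = embedding.ndim == 1
    out = evaluator.predict(embedding)
    return float(out[0]) if single else out


def filter_by_quality(
    spectra: Sequence[Spectrum],
    predicted: Sequence[float],
    retain_fraction: float,
) -> list[Spectrum]:
    """Keep the fraction of spectra with the lowest predicted MSE.

    Ties are broken by spectrum_id; the returned subset preserves the input
    order.  ``retain_fraction=1`` is the identity.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    if not spectra:
        raise ValueError("no spectra to filter")
    if len(spectra) != len(predicted):
        raise ValueError("one predicted MSE per spectrum is required")
    n_keep = max(1, int(round(retain_fraction * len(spectra))))
    order = sorted(
        range(len(spectra)), key=lambda i: (predicted[i], spectra[i].spectrum_id)
    )
    kept = sorted(order[:n_keep])
    return [spectra[i] for i in kept]
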
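"""Spectrum featurization: m/z binning, metadata encoding and augmentation.

The model input is the concatenation of an encoded-metadata channel and a
binned fragment channel.  Fragments are binned on a fixed 0.1 Da grid over
10 <= m/z < 1000 (9900 bins by default); intensities are normalized to the
base peak and square-root transformed to damp dominant signals.  Metadata
encoders map numerical fields to values near 1 (scaling divisor) and
categorical fields to one-hot vectors in a declared order.

Training-time augmentation perturbs only the fragment channel: random
removal of a fraction of occupied bins, multiplicative intensity jitter,
and low-intensity noise peaks in empty bins, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .spectra_io import Spectrum

__all__ = [
    "BinningScheme",
    "NumericalEncoder",
    "CategoricalEncoder",
    "MetadataSpec",
    "AugmentConfig",
    "default_metadata_spec",
    "bin_peaks",
    "encode_metadata",
    "featurize",
    "augment",
]


@dataclass(frozen=True)
class BinningScheme:
    """Fixed-width m/z binning grid, left-closed right-open intervals."""

    bin_width: float = 0.1
    mz_min: float = 10.0
    mz_max: float = 1000.0
    combine: str = "max"  # how multiple peaks in one bin merge: "max" or "sum"

    @property
    def n_bins(self) -> int:
        return round((self.mz_max - self.mz_min) / self.bin_width)

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "mz_min": self.mz_min,
            "mz_max": self.mz_max,
            "combine": self.combine,
        }


@dataclass(frozen=True)
class NumericalEncoder:
    """Scalar metadata field divided by a fixed divisor (brings values near 1)."""

    name: str
    divisor: float = 1.0

    @property
    def width(self) -> int:
        return 1


@dataclass(frozen=True)
class CategoricalEncoder:
    """One-hot encoded categorical metadata field with a declared category order."""

    name: str
    categories: tuple[str, ...]

    @property
    def width(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class MetadataSpec:
    """Ordered list of metadata encoders; output width is the sum of encoder widths."""

    encoders: tuple = ()

    @property
    def width(self) -> int:
        return sum(e.width for e in self.encoders)

    def to_dict(self) -> dict:
        out = []
        for e in self.encoders:
            if isinstance(e, NumericalEncoder):
                out.append({"kind": "numerical", "name": e.name, "divisor": e.divisor})
            else:
                out.append(
                    {"kind": "categorical", "name": e.name,
                     "categories": list(e.categories)}
                )
        return {"encoders": out}

    @classmethod
    def from_dict(cls, data: dict) -> "MetadataSpec":
        encoders = []
        for e in data["encoders"]:
            if e["kind"] == "numerical":
                encoders.append(NumericalEncoder(e["name"], e["divisor"]))
            else:
                encoders.append(CategoricalEncoder(e["name"], tuple(e["categories"])))
        return cls(encoders=tuple(encoders))


def default_metadata_spec() -> MetadataSpec:
    """Precursor m/z scaled by 1000 plus ionization mode one-hot: 3 dims."""
    return MetadataSpec(
        encoders=(
            NumericalEncoder("precursor_mz", 1000.0),
            CategoricalEncoder("ionmode", ("positive", "negative")),
        )
    )


@dataclass(frozen=True)
class AugmentConfig:
    """Magnitudes of training-time fragment-channel augmentation."""

    removal_max: float = 0.2
    intensity_jitter: float = 0.2
    noise_intensity: float = 0.02
    noise_peaks_max: int = 10

    def __post_init__(self) -> None:
        for name in ("removal_max", "intensity_jitter", "noise_intensity"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "removal_max": self.removal_max,
            "intensity_jitter": self.intensity_jitter,
            "noise_intensity": self.noise_intensity,
            "noise_peaks_max": self.noise_peaks_max,
        }


def bin_peaks(spectrum: Spectrum, scheme: BinningScheme = BinningScheme()) -> np.ndarray:
    """Dense binned fragment vector of length ``scheme.n_bins``.

    In-range intensities are normalized to the base peak (max = 1) and then
    square-root transformed; each peak lands in bin
    ``floor((mz - mz_min)/bin_width)`` and coinciding peaks merge by the
    scheme's ``combine`` rule.
    """
    mz = spectrum.peaks[:, 0]
    intensity = spectrum.peaks[:, 1]
    mask = (mz >= scheme.mz_min) & (mz < scheme.mz_max) & (intensity > 0)
    if not mask.any():
        raise ValueError(
            f"spectrum {spectrum.spectrum_id!r} has no in-range peaks to normalize"
        )
    mz, intensity = mz[mask], intensity[mask]
    transformed = np.sqrt(intensity / intensity.max())
    indices = np.floor((mz - scheme.mz_min) / scheme.bin_width).astype(int)
    indices = np.clip(indices, 0, scheme.n_bins - 1)
    binned = np.zeros(scheme.n_bins, dtype=float)
    if scheme.combine == "max":
        np.maximum.at(binned, indices, transformed)
    elif scheme.combine == "sum":
        np.add.at(binned, indices, transformed)
    else:
        raise ValueError(f"unknown combine rule {scheme.combine!r}")
    return binned


def encode_metadata(spectrum: Spectrum, spec: MetadataSpec) -> np.ndarray:
    """Encode scan metadata per the spec's encoder order into a dense vector."""
    parts: list[np.ndarray] = []
    for encoder in spec.encoders:
        value = getattr(spectrum, encoder.name, None)
        if value is None:
            value = spectrum.extra.get(encoder.name)
        if value is None:
            raise ValueError(
                f"spectrum {spectrum.spectrum_id!r} lacks metadata field "
                f"{encoder.name!r} required by the model"
            )
        if isinstance(encoder, NumericalEncoder):
            parts.append(np.array([float(value) / encoder.divisor]))
        else:
            if value not in encoder.categories:
                raise ValueError(
                    f"spectrum {spectrum.spectrum_id!r}: value {value!r} for "
                    f"{encoder.name!r} not in categories {encoder.categories}"
                )
            one_hot = np.zeros(len(encoder.categories))
            one_hot[encoder.categories.index(value)] = 1.0
            parts.append(one_hot)
    if not parts:
        return np.zeros(0)
    return np.concatenate(parts)


def featurize(
    spectrum: Spectrum,
    scheme: BinningScheme = BinningScheme(),
    spec: MetadataSpec | None = None,
) -> np.ndarray:
    """Model input vector: [metadata || binned fragments]."""
    if spec is None:
        spec = default_metadata_spec()
    return np.concatenate([encode_metadata(spectrum, spec), bin_peaks(spectrum, scheme)])


def augment(
    binned: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Perturb a binned fragment vector: removal, jitter, then noise peaks.

    Removal deletes a uniformly drawn fraction (up to ``removal_max``) of the
    occupied bins; jitter rescales each surviving occupied bin by a factor in
    [1 - intensity_jitter, 1 + intensity_jitter]; noise fills up to
    ``noise_peaks_max`` empty bins with intensity in (0, noise_intensity].
    The metadata channel is never passed through this function.
    """
    out = binned.copy()
    nonzero = np.flatnonzero(out)
    if nonzero.size and cfg.removal_max > 0:
        fraction = rng.uniform(0, cfg.removal_max)
        n_remove = int(np.floor(fraction * nonzero.size))
        if n_remove:
            remove = rng.choice(nonzero, size=n_remove, replace=False)
            out[remove] = 0.0
    survivors = np.flatnonzero(out)
    if survivors.size and cfg.intensity_jitter > 0:
        factors = rng.uniform(
            1 - cfg.intensity_jitter, 1 + cfg.intensity_jitter, size=survivors.size
        )
        out[survivors] *= factors
    if cfg.noise_peaks_max > 0 and cfg.noise_intensity > 0:
        n_noise = int(rng.integers(0, cfg.noise_peaks_max + 1))
        empty = np.flatnonzero(out == 0)
        n_noise = min(n_noise, empty.size)
        if n_noise:
            targets = rng.choice(empty, size=n_noise, replace=False)
            out[targets] = (1.0 - rng.random(n_noise)) * cfg.noise_intensity
    return out
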
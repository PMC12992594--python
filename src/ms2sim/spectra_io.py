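"""Reading, cleaning and splitting annotated MS/MS spectral libraries.

A library is a flat list of :class:`Spectrum` objects.  Spectra carry a peak
list (fragment m/z, intensity), scan metadata (precursor m/z, ionization
mode, adduct, instrument) and an optional structure annotation (SMILES and/or
InChIKey).  Train/validation/test splitting is done on unique 2-D structures
(first InChIKey block) so that no molecule leaks across partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "LibrarySplit",
    "MGFParseError",
    "normalize_ionmode",
    "read_mgf",
    "write_mgf",
    "read_msp",
    "clean_spectra",
    "split_library",
    "write_split_manifest",
]

_POSITIVE = {"positive", "pos", "+"}
_NEGATIVE = {"negative", "neg", "-"}


def normalize_ionmode(value: str | None) -> str | None:
    """Map free-text polarity strings onto ``"positive"``/``"negative"``.

    Unrecognized strings map to ``None`` (missing), never raise.
    """
    if value is None:
        return None
    v = value.strip().lower()
    if v in _POSITIVE:
        return "positive"
    if v in _NEGATIVE:
        return "negative"
    return None


@dataclass
class Spectrum:
    """One tandem mass spectrum: peak list plus scan/structure metadata.

    Peaks are stored as an (n, 2) float array of (m/z, intensity), sorted by
    ascending m/z.  Intensities are in arbitrary (instrument) units and are
    only required to be non-negative; normalization happens at featurization
    time.
    """

    peaks: np.ndarray
    precursor_mz: float | None = None
    ionmode: str | None = None
    adduct: str | None = None
    instrument: str | None = None
    smiles: str | None = None
    inchikey: str | None = None
    spectrum_id: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        peaks = np.atleast_2d(np.asarray(self.peaks, dtype=float))
        if peaks.size == 0:
            peaks = np.empty((0, 2), dtype=float)
        if peaks.shape[1] != 2:
            raise ValueError("peaks must be an (n, 2) array of (mz, intensity)")
        if np.any(peaks[:, 0] <= 0):
            raise ValueError(f"spectrum {self.spectrum_id!r}: all m/z must be > 0")
        if np.any(peaks[:, 1] < 0):
            raise ValueError(f"spectrum {self.spectrum_id!r}: intensities must be >= 0")
        order = np.argsort(peaks[:, 0], kind="stable")
        self.peaks = peaks[order]
        if self.precursor_mz is not None and self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.spectrum_id!r}: precursor_mz must be > 0")
        self.ionmode = normalize_ionmode(self.ionmode)

    @property
    def n_peaks(self) -> int:
        return int(self.peaks.shape[0])

    @property
    def inchikey14(self) -> str | None:
        if self.inchikey is None:
            return None
        return self.inchikey[:14]


class MGFParseError(ValueError):
    """Raised for structurally invalid MGF input; message carries the line number."""


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF (Mascot generic format) file into a list of spectra.

    Each ``BEGIN IONS``/``END IONS`` block becomes one :class:`Spectrum`.
    Recognized metadata keys: PEPMASS, IONMODE (or CHARGE sign), ADDUCT,
    SMILES, INCHIKEY, INSTRUMENT, TITLE (used as spectrum_id).  Unrecognized
    ``KEY=value`` lines are preserved verbatim in ``Spectrum.extra``.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    in_block = False
    block_start = 0
    meta: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.upper() == "BEGIN IONS":
                if in_block:
                    raise MGFParseError(
                        f"{path}:{lineno}: BEGIN IONS inside an open block "
                        f"(block started at line {block_start} has no END IONS)"
                    )
                in_block, block_start, meta, peaks = True, lineno, {}, []
            elif line.upper() == "END IONS":
                if not in_block:
                    raise MGFParseError(f"{path}:{lineno}: END IONS without BEGIN IONS")
                spectra.append(_spectrum_from_block(meta, peaks, len(spectra)))
                in_block = False
            elif in_block:
                if "=" in line:
                    key, _, value = line.partition("=")
                    meta[key.strip().upper()] = value.strip()
                else:
                    parts = line.split()
                    try:
                        mz, intensity = float(parts[0]), float(parts[1])
                    except (ValueError, IndexError):
                        raise MGFParseError(
                            f"{path}:{lineno}: non-numeric peak line {line!r}"
                        ) from None
                    peaks.append((mz, intensity))
    if in_block:
        raise MGFParseError(
            f"{path}: block starting at line {block_start} is missing END IONS"
        )
    return spectra


def _spectrum_from_block(
    meta: dict[str, str], peaks: list[tuple[float, float]], index: int
) -> Spectrum:
    known = {"PEPMASS", "IONMODE", "ADDUCT", "SMILES", "INCHIKEY", "INSTRUMENT",
             "TITLE", "CHARGE"}
    precursor = None
    if "PEPMASS" in meta:
        precursor = float(meta["PEPMASS"].split()[0])
    ionmode = normalize_ionmode(meta.get("IONMODE"))
    if ionmode is None and "CHARGE" in meta:
        charge = meta["CHARGE"]
        ionmode = "negative" if charge.endswith("-") else "positive"
    return Spectrum(
        peaks=np.array(peaks, dtype=float).reshape(-1, 2),
        precursor_mz=precursor,
        ionmode=ionmode,
        adduct=meta.get("ADDUCT"),
        instrument=meta.get("INSTRUMENT"),
        smiles=meta.get("SMILES"),
        inchikey=meta.get("INCHIKEY"),
        spectrum_id=meta.get("TITLE", f"spectrum_{index}"),
        extra={k: v for k, v in meta.items() if k not in known},
    )


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; peak values to 6 decimals, metadata as KEY=value."""
    path = Path(path)
    with path.open("w") as handle:
        for spectrum in spectra:
            handle.write("BEGIN IONS\n")
            handle.write(f"TITLE={spectrum.spectrum_id}\n")
            if spectrum.precursor_mz is not None:
                handle.write(f"PEPMASS={spectrum.precursor_mz:.6f}\n")
            for key, value in (
                ("IONMODE", spectrum.ionmode),
                ("ADDUCT", spectrum.adduct),
                ("INSTRUMENT", spectrum.instrument),
                ("SMILES", spectrum.smiles),
                ("INCHIKEY", spectrum.inchikey),
            ):
                if value is not None:
                    handle.write(f"{key}={value}\n")
            for key, value in spectrum.extra.items():
                handle.write(f"{key}={value}\n")
            for mz, intensity in spectrum.peaks:
                handle.write(f"{mz:.6f} {intensity:.6f}\n")
            handle.write("END IONS\n\n")


def read_msp(path: str | Path) -> list[Spectrum]:
    """Read an MSP library (NAME / PRECURSORMZ / Num Peaks dialect) via matchms."""
    from matchms.importing import load_from_msp

    spectra = []
    for i, ms in enumerate(load_from_msp(str(path), metadata_harmonization=True)):
        if ms is None:
            continue
        meta = ms.metadata
        spectra.append(
            Spectrum(
                peaks=np.column_stack([ms.peaks.mz, ms.peaks.intensities]),
                precursor_mz=meta.get("precursor_mz"),
                ionmode=normalize_ionmode(meta.get("ionmode")),
                adduct=meta.get("adduct"),
                instrument=meta.get("instrument_type") or meta.get("instrument"),
                smiles=meta.get("smiles"),
                inchikey=meta.get("inchikey"),
                spectrum_id=meta.get("compound_name") or f"spectrum_{i}",
            )
        )
    return spectra


def clean_spectra(
    spectra: Sequence[Spectrum],
    min_fragments: int = 4,
    mz_range: tuple[float, float] = (10.0, 1000.0),
    for_training: bool = False,
) -> list[Spectrum]:
    """Basic quality filtering: peak-count and m/z-range thresholds.

    Peaks outside ``mz_range`` (left-closed, right-open) are removed; a
    spectrum survives only if strictly more than ``min_fragments`` peaks
    remain.  With ``for_training=True``, spectra lacking an ionization mode
    or precursor m/z are additionally dropped.  Filtering never raises.
    """
    if min_fragments < 0:
        raise ValueError("min_fragments must be >= 0")
    lo, hi = mz_range
    kept: list[Spectrum] = []
    for spectrum in spectra:
        mask = (spectrum.peaks[:, 0] >= lo) & (spectrum.peaks[:, 0] < hi)
        if int(mask.sum()) <= min_fragments:
            continue
        if for_training and (spectrum.ionmode is None or spectrum.precursor_mz is None):
            continue
        if mask.all():
            kept.append(spectrum)
        else:
            trimmed = Spectrum(
                peaks=spectrum.peaks[mask],
                precursor_mz=spectrum.precursor_mz,
                ionmode=spectrum.ionmode,
                adduct=spectrum.adduct,
                instrument=spectrum.instrument,
                smiles=spectrum.smiles,
                inchikey=spectrum.inchikey,
                spectrum_id=spectrum.spectrum_id,
                extra=dict(spectrum.extra),
            )
            kept.append(trimmed)
    return kept


@dataclass
class LibrarySplit:
    """Molecule-disjoint train/validation/test partition of a library."""

    train: list[Spectrum]
    validation: list[Spectrum]
    test: list[Spectrum]
    train_molecules: set[str]
    validation_molecules: set[str]
    test_molecules: set[str]


def split_library(
    spectra: Sequence[Spectrum], fraction: float = 1 / 20, seed: int = 0
) -> LibrarySplit:
    """Split a library into train/validation/test on unique molecules.

    Per ionization mode, ``fraction`` of that mode's unique molecules (first
    InChIKey block) is drawn for validation and an independent, disjoint
    ``fraction`` for test; every spectrum of a selected molecule — in either
    mode — leaves the training set.  At least one molecule is drawn per
    partition per mode.  Deterministic given ``seed``.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    missing = [s.spectrum_id for s in spectra if s.inchikey14 is None]
    if missing:
        raise ValueError(
            "spectra lacking an InChIKey cannot be split by molecule: "
            + ", ".join(missing)
        )
    rng = np.random.default_rng(seed)
    val_molecules: set[str] = set()
    test_molecules: set[str] = set()
    for mode in ("positive", "negative"):
        mols = sorted({s.inchikey14 for s in spectra if s.ionmode == mode})
        mols = [m for m in mols if m not in val_molecules and m not in test_molecules]
        if not mols:
            continue
        n_draw = max(1, int(len(mols) * fraction))
        chosen = rng.choice(len(mols), size=min(2 * n_draw, len(mols)), replace=False)
        val_molecules.update(mols[i] for i in chosen[:n_draw])
        test_molecules.update(mols[i] for i in chosen[n_draw : 2 * n_draw])
    train, validation, test = [], [], []
    for spectrum in spectra:
        key = spectrum.inchikey14
        if key in val_molecules:
            validation.append(spectrum)
        elif key in test_molecules:
            test.append(spectrum)
        else:
            train.append(spectrum)
    return LibrarySplit(
        train=train,
        validation=validation,
        test=test,
        train_molecules={s.inchikey14 for s in train},
        validation_molecules=val_molecules,
        test_molecules=test_molecules,
    )


def write_split_manifest(split: LibrarySplit, path: str | Path) -> None:
    """Persist the molecule membership of a split as JSON."""
    manifest = {
        "train": sorted(split.train_molecules),
        "validation": sorted(split.validation_molecules),
        "test": sorted(split.test_molecules),
        "n_spectra": {
            "train": len(split.train),
            "validation": len(split.validation),
            "test": len(split.test),
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
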
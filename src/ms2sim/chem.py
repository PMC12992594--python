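"""Structure identity, molecular fingerprints and Tanimoto chemical similarity.

Ground-truth chemical similarity is the Tanimoto score between binary
path-based (daylight-like) fingerprints of length 4096, computed per unique
2-D structure.  Two structures are the same molecule when the first 14
characters of their InChIKeys (the connectivity block) agree, i.e.
stereochemistry is ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FINGERPRINT_BITS",
    "MoleculeRecord",
    "TanimotoMatrix",
    "inchikey14",
    "fingerprint",
    "tanimoto",
    "tanimoto_matrix",
    "records_from_spectra",
    "save_fingerprints",
    "load_fingerprints",
]

FINGERPRINT_BITS = 4096


def inchikey14(inchikey: str) -> str:
    """First InChIKey block (14 chars): 2-D structure identity, stereochemistry ignored."""
    if len(inchikey) < 14:
        raise ValueError(f"InChIKey too short ({len(inchikey)} chars): {inchikey!r}")
    return inchikey[:14]


def fingerprint(smiles: str, n_bits: int = FINGERPRINT_BITS) -> np.ndarray:
    """Daylight-like binary path fingerprint of a SMILES string.

    Uses RDKit's topological path fingerprint with default path lengths;
    canonicalization inside RDKit guarantees that equivalent SMILES of the
    same structure yield identical bit vectors.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    bits = Chem.RDKFingerprint(mol, fpSize=n_bits)
    vector = np.zeros(n_bits, dtype=np.uint8)
    vector[list(bits.GetOnBits())] = 1
    return vector


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto score |a AND b| / |a OR b| between two binary vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("Tanimoto score is undefined for an all-zero fingerprint")
    intersection = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    return intersection / union


@dataclass
class MoleculeRecord:
    """A unique 2-D structure: identity, fingerprint and its spectra."""

    inchikey14: str
    fingerprint: np.ndarray
    spectrum_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fingerprint = np.asarray(self.fingerprint, dtype=np.uint8)
        if self.fingerprint.ndim != 1:
            raise ValueError("fingerprint must be a 1-D bit vector")
        if not self.fingerprint.any():
            raise ValueError(
                f"molecule {self.inchikey14}: fingerprint has no set bits"
            )


@dataclass
class TanimotoMatrix:
    """Symmetric all-vs-all Tanimoto score matrix over molecules."""

    inchikeys: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.index = {key: i for i, key in enumerate(self.inchikeys)}

    def score(self, key_a: str, key_b: str) -> float:
        return float(self.scores[self.index[key_a], self.index[key_b]])

    @property
    def n(self) -> int:
        return len(self.inchikeys)


def tanimoto_matrix(records: Sequence[MoleculeRecord]) -> TanimotoMatrix:
    """Pairwise Tanimoto matrix; vectorized via bit-count linear algebra."""
    if len(records) < 2:
        raise ValueError("need at least two molecules for a Tanimoto matrix")
    keys = [r.inchikey14 for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate inchikey14 among molecule records")
    bits = np.stack([r.fingerprint for r in records]).astype(np.float64)
    intersection = bits @ bits.T
    popcount = bits.sum(axis=1)
    union = popcount[:, None] + popcount[None, :] - intersection
    scores = intersection / union
    return TanimotoMatrix(inchikeys=keys, scores=scores)


def records_from_spectra(spectra, n_bits: int = FINGERPRINT_BITS) -> list[MoleculeRecord]:
    """Group annotated spectra into one record per unique 2-D structure.

    Fingerprints come from the first parseable SMILES seen for a molecule.
    Spectra without an InChIKey or without any parseable SMILES are skipped.
    """
    by_molecule: dict[str, MoleculeRecord] = {}
    pending_smiles: dict[str, str] = {}
    for spectrum in spectra:
        key = spectrum.inchikey14
        if key is None:
            continue
        if key not in by_molecule:
            if spectrum.smiles is None:
                pending_smiles.setdefault(key, "")
                continue
            try:
                fp = fingerprint(spectrum.smiles, n_bits=n_bits)
            except ValueError:
                continue
            by_molecule[key] = MoleculeRecord(key, fp, [])
        by_molecule[key].spectrum_ids.append(spectrum.spectrum_id)
    return list(by_molecule.values())


def save_fingerprints(records: Sequence[MoleculeRecord], directory: str | Path) -> None:
    """Persist fingerprints binary-packed (one row per molecule) plus a JSON index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    packed = np.packbits(
        np.stack([r.fingerprint for r in records]).astype(np.uint8), axis=1
    )
    np.save(directory / "fingerprints.npy", packed)
    index = {
        "inchikeys": [r.inchikey14 for r in records],
        "n_bits": int(records[0].fingerprint.size),
        "spectrum_ids": {r.inchikey14: r.spectrum_ids for r in records},
    }
    (directory / "fingerprints.json").write_text(json.dumps(index))


def load_fingerprints(directory: str | Path) -> list[MoleculeRecord]:
    directory = Path(directory)
    index = json.loads((directory / "fingerprints.json").read_text())
    packed = np.load(directory / "fingerprints.npy")
    bits = np.unpackbits(packed, axis=1)[:, : index["n_bits"]]
    return [
        MoleculeRecord(key, bits[i], index["spectrum_ids"].get(key, []))
        for i, key in enumerate(index["inchikeys"])
    ]
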
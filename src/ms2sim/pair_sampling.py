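"""Balanced molecule-pair selection and the training-time spectrum-pair stream.

Tanimoto scores across all molecule pairs of a spectral library are heavily
skewed: low scores outnumber high scores by orders of magnitude.  Training a
similarity regressor on uniformly drawn pairs would therefore see almost no
informative high-similarity examples.  The selection algorithm here draws an
exactly equal number of molecule pairs from each of ``n_bins`` equally
spaced Tanimoto bins, while greedily equalizing how often each individual
molecule is sampled:

* bins are visited round-robin, one pair per bin per cycle;
* within a bin the globally least-sampled molecule that still has a partner
  in the bin is chosen first, then its least-sampled partner;
* molecule pairs may be re-drawn (resampling) when a bin is sparse;
* a running sampling cap (``cap_multiplier`` x the mean per-molecule count)
  skips over-sampled molecules whenever alternatives exist, which bounds the
  per-molecule count disparity.

During training, the fixed list of selected molecule pairs is looped every
epoch while the concrete spectra for each molecule are re-drawn uniformly at
random, so repeated visits to a pair see fresh spectrum combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .chem import TanimotoMatrix
from .spectra_io import Spectrum

__all__ = [
    "SamplingConfig",
    "SelectedPairs",
    "assign_bin",
    "select_balanced_pairs",
    "sampling_report",
    "PairGenerator",
]


def assign_bin(score: float, n_bins: int = 10) -> int:
    """Equally spaced, left-closed Tanimoto bin index; 1.0 joins the last bin."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"Tanimoto score out of range [0, 1]: {score}")
    return min(int(np.floor(score * n_bins)), n_bins - 1)


@dataclass(frozen=True)
class SamplingConfig:
    """Knobs of the balanced pair-selection algorithm."""

    n_bins: int = 10
    pairs_per_bin: int = 100
    cap_multiplier: float = 1.10
    allow_resampling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.cap_multiplier <= 1:
            raise ValueError("cap_multiplier must be > 1")

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "pairs_per_bin": self.pairs_per_bin,
            "cap_multiplier": self.cap_multiplier,
            "allow_resampling": self.allow_resampling,
            "seed": self.seed,
        }


@dataclass
class SelectedPairs:
    """Balanced training set of molecule pairs with scores and bin labels."""

    pairs: list[tuple[str, str, float, int]]
    molecule_counts: dict[str, int]
    bin_counts: np.ndarray
    n_bins: int

    def __len__(self) -> int:
        return len(self.pairs)


def _availability(
    tm: TanimotoMatrix, n_bins: int
) -> tuple[list[dict[int, np.ndarray]], list[bool]]:
    """Per bin: molecule index -> array of partner indices with a score in the bin."""
    n = tm.n
    iu, ju = np.triu_indices(n, k=1)
    scores = tm.scores[iu, ju]
    bins = np.minimum(np.floor(scores * n_bins).astype(int), n_bins - 1)
    per_bin: list[dict[int, list[int]]] = [dict() for _ in range(n_bins)]
    for i, j, b in zip(iu, ju, bins):
        per_bin[b].setdefault(int(i), []).append(int(j))
        per_bin[b].setdefault(int(j), []).append(int(i))
    out: list[dict[int, np.ndarray]] = []
    has_distinct: list[bool] = []
    for b in range(n_bins):
        out.append({m: np.array(p, dtype=int) for m, p in per_bin[b].items()})
        has_distinct.append(len(per_bin[b]) > 0)
    return out, has_distinct


def select_balanced_pairs(tm: TanimotoMatrix, cfg: SamplingConfig) -> SelectedPairs:
    """Draw an exactly equal number of molecule pairs per Tanimoto bin.

    Bins are filled round-robin.  Within a bin, the globally least-sampled
    molecule that still has an uncapped partner is chosen first, then its
    least-sampled (uncapped) partner; a molecule is capped once its count
    exceeds ``cap_multiplier`` x the running mean count, and capped pairs
    are skipped whenever the bin offers an alternative.  Raises if any bin
    has no available pair at all (for the top bin, same-molecule pairs at
    Tanimoto 1.0 serve as a fallback when no distinct-molecule pair lands
    there).
    """
    n_bins = cfg.n_bins
    rng = np.random.default_rng(cfg.seed)
    avail, has_distinct = _availability(tm, n_bins)
    top_bin = n_bins - 1
    for b in range(n_bins):
        if not has_distinct[b] and b != top_bin:
            lo, hi = b / n_bins, (b + 1) / n_bins
            raise ValueError(
                f"Tanimoto bin {b} ([{lo:.2f}, {hi:.2f})) has no available "
                "molecule pairs; the library cannot populate all bins"
            )
    counts = np.zeros(tm.n, dtype=np.int64)
    total = 0
    n_sampled = 0  # molecules with count > 0
    pairs: list[tuple[str, str, float, int]] = []
    bin_counts = np.zeros(n_bins, dtype=np.int64)
    keys = tm.inchikeys
    mol_arrays = [
        np.fromiter(avail[b].keys(), dtype=int) if avail[b] else None
        for b in range(n_bins)
    ]
    all_molecules = np.arange(tm.n)

    def least_of(cands: np.ndarray) -> int:
        least = cands[counts[cands] == counts[cands].min()]
        return int(least[rng.integers(least.size)]) if least.size > 1 else int(least[0])

    used: set[tuple[int, int]] = set()

    def fresh(mol: int, partners: np.ndarray) -> np.ndarray:
        if cfg.allow_resampling:
            return partners
        keep = [p for p in partners
                if (min(mol, int(p)), max(mol, int(p))) not in used]
        return np.array(keep, dtype=int)

    def pick_pair(b: int) -> tuple[int, int]:
        cap = np.inf if total == 0 else cfg.cap_multiplier * (total / n_sampled)
        mols = mol_arrays[b]
        # candidates ordered by sampling count, seeded shuffle breaking ties
        order = mols[np.lexsort((rng.random(mols.size), counts[mols]))]
        for mol in order:
            if counts[mol] > cap:
                break  # sorted by count: every remaining candidate is capped too
            partners = fresh(int(mol), avail[b][int(mol)])
            if not partners.size:
                continue
            uncapped = partners[counts[partners] <= cap]
            if uncapped.size:
                return int(mol), least_of(uncapped)
        # every pair in the bin touches a capped molecule: forced greedy pick
        for mol in order:
            partners = fresh(int(mol), avail[b][int(mol)])
            if partners.size:
                return int(mol), least_of(partners)
        raise ValueError(
            f"Tanimoto bin {b} has no unused pairs left and resampling is disabled"
        )

    for _ in range(cfg.pairs_per_bin):
        for b in range(n_bins):
            if has_distinct[b]:
                first, second = pick_pair(b)
                score = float(tm.scores[first, second])
            else:  # top bin, self-pair fallback (Tanimoto 1.0 with itself)
                first = least_of(all_molecules)
                second = first
                score = 1.0
            if not cfg.allow_resampling and first != second:
                used.add((min(first, second), max(first, second)))
            pairs.append((keys[first], keys[second], score, b))
            for m in (first, second):
                if counts[m] == 0:
                    n_sampled += 1
                counts[m] += 1
                total += 1
            bin_counts[b] += 1

    molecule_counts = {keys[i]: int(c) for i, c in enumerate(counts) if c > 0}
    return SelectedPairs(
        pairs=pairs,
        molecule_counts=molecule_counts,
        bin_counts=bin_counts,
        n_bins=n_bins,
    )


def sampling_report(selected: SelectedPairs) -> dict:
    """Summary of sampling balance: per-bin/per-molecule counts and disparity."""
    if not selected.pairs:
        raise ValueError("no selected pairs to report on")
    counts = np.array(list(selected.molecule_counts.values()), dtype=float)
    disparity = 100.0 * (counts.max() - counts.min()) / counts.max()
    n_unique = len({(a, b) if a <= b else (b, a) for a, b, _, _ in selected.pairs})
    return {
        "n_pairs": len(selected.pairs),
        "bin_counts": [int(c) for c in selected.bin_counts],
        "molecule_counts": dict(selected.molecule_counts),
        "max_disparity_percent": float(disparity),
        "resampling_rate": 1.0 - n_unique / len(selected.pairs),
    }


class PairGenerator:
    """Epoch-wise stream of (Spectrum, Spectrum, tanimoto) training examples.

    Each epoch shuffles the fixed molecule-pair list and draws one spectrum
    per molecule uniformly at random, so a molecule pair contributes fresh
    spectrum combinations every epoch.  Fully deterministic given ``seed``.
    """

    def __init__(
        self,
        selected: SelectedPairs,
        spectra_index: Mapping[str, Sequence[Spectrum]],
        seed: int = 0,
    ) -> None:
        for key in selected.molecule_counts:
            if not spectra_index.get(key):
                raise ValueError(f"molecule {key} has no spectra in the index")
        self.selected = selected
        self.spectra_index = spectra_index
        self._rng = np.random.default_rng(seed)

    def __len__(self) -> int:
        return len(self.selected)

    def epoch(self) -> Iterator[tuple[Spectrum, Spectrum, float]]:
        """One pass over the (shuffled) molecule pairs with fresh spectrum draws."""
        order = self._rng.permutation(len(self.selected.pairs))
        for idx in order:
            mol_a, mol_b, score, _ = self.selected.pairs[idx]
            spectra_a = self.spectra_index[mol_a]
            spectra_b = self.spectra_index[mol_b]
            spec_a = spectra_a[self._rng.integers(len(spectra_a))]
            spec_b = spectra_b[self._rng.integers(len(spectra_b))]
            yield spec_a, spec_b, score

    def __iter__(self) -> Iterator[tuple[Spectrum, Spectrum, float]]:
        return self.epoch()
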
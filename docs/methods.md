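# Methods

## Task and model

The package predicts the chemical similarity of the molecules behind two
tandem mass spectra. Ground truth is the Tanimoto score between binary
molecular fingerprints: RDKit's topological path ("daylight-like")
fingerprint at 4096 bits, computed once per unique 2-D structure, where two
structures are "the same molecule" when the first 14 characters of their
InChIKeys agree (stereochemistry ignored). 4096 bits is the default and is
configurable; results are not comparable across fingerprint lengths.

A Siamese network maps each featurized spectrum to an embedding; the
predicted similarity is the cosine of the pair of embeddings, regressed on
the true Tanimoto score with mean-squared-error loss. Both arms share
weights exactly. The reference architecture is a single dense hidden layer
of 10,000 ReLU units followed by a 500-unit Tanh embedding layer, with no
dropout and no batch normalization. The desk-scale profile used throughout
the tests is the same shape at 512 hidden units and a 64-dim embedding.
Because the output activation is Tanh, cosine predictions may be negative
while Tanimoto is non-negative; predictions are deliberately not clamped —
the squared-error loss itself pushes dissimilar pairs apart, and clamping
would zero the gradient exactly where it is needed.

### Featurization

* Fragment channel: bins of 0.1 Da on 10 ≤ m/z < 1000 (left-closed,
  right-open), 9900 bins, all bins always present. Intensities are first
  normalized to the base peak and then square-root transformed; the
  normalization step is a package choice (it makes intensities comparable
  across instruments) and is configurable, as is the rule that merges
  multiple peaks in one bin (max of transformed intensities by default,
  sum as an alternative; max is robust to centroiding artifacts).
* Metadata channel: an ordered list of encoders. Numerical fields are
  divided by a fixed divisor to land near 1 (precursor m/z / 1000);
  categorical fields are one-hot in declared order (ionization mode:
  positive, negative). The default spec contributes 3 input values; an
  empty spec yields a fragments-only model.
* Augmentation (training only, fragment channel only), applied in the
  order removal → jitter → noise: delete a uniformly drawn fraction (up to
  0.2) of occupied bins; rescale each surviving occupied bin by a factor
  uniform in [0.8, 1.2]; add up to 10 noise peaks in empty bins with
  intensity in (0, 0.02]. The magnitudes follow the reference settings;
  the operator order and the noise-peak count are package choices pinned
  in the settings JSON.

### Training

Adam with learning rate 1e-4 (reference profile) or 1e-3 (desk profile),
batch size 32, fully seeded; weight init is Glorot-uniform from a seeded
generator, so two runs with the same seed produce bit-identical histories.
Validation loss is computed with the benchmark protocol (molecule-pair
averaging, Tanimoto-binned) on a fixed list of validation spectrum pairs;
early stopping restores the best weights after the configured patience.
At desk scale the model overfits its training pairs within a few epochs
while generalization to held-out molecules peaks early — the early-stopping
default matters more than the epoch budget.

## Balanced pair selection

Tanimoto scores over all molecule pairs of a library are extremely skewed
(low scores outnumber high scores by orders of magnitude), so training
pairs are drawn per similarity bin: ten equally spaced bins on [0, 1],
score 1.0 assigned to the top bin. Selection visits bins round-robin, one
pair per bin per cycle, so per-bin counts are exactly equal at every
moment. Within a bin the globally least-sampled molecule that still has a
partner is selected, then its least-sampled partner; ties break uniformly
at random from the run seed. Molecule pairs may be re-drawn (resampling)
when a bin is sparse; an optional strict mode forbids reuse and raises when
a bin is exhausted.

The per-molecule sampling cap: a molecule is "capped" once its count
exceeds `cap_multiplier` × the running mean count (total selections /
molecules sampled so far). The cap is enforced at **pair level** — a pair
is skipped whenever either of its molecules is capped and the bin offers an
uncapped alternative; if every pair in the bin touches a capped molecule
the least-sampled pair is taken anyway (per-bin balance is never
sacrificed). Pair-level enforcement is what makes the cap effective: the
molecules that overshoot are not the ones the greedy rule *chooses* but the
ones it is *forced onto* as sole partners in sparse bins, and only skipping
the whole pair redirects those picks. The default multiplier is 1.10; on
the standard synthetic library (300 molecules, all bins populated, 500
pairs per bin) this bounds the per-molecule count disparity
100·(max−min)/max below 15 % across seeds, with typical values near 11 %.
On libraries with densely populated bins the count-greedy rule alone
already achieves this; the cap is the safeguard for skewed topologies
(e.g. a hub molecule that is the only high-similarity partner of many
others), where it demonstrably reduces disparity.

During training a generator loops the fixed selected-pair list every epoch,
shuffling pair order and re-drawing one spectrum per molecule uniformly at
random, so repeated pairs contribute fresh spectrum combinations.

## Embedding-quality estimation

Each training spectrum is labeled with its realized prediction error: the
MSE between predicted and true similarity over 999 randomly sampled partner
spectra (without replacement, a fresh seeded stream per spectrum; smaller
libraries use all available partners). A regressor learns to predict this
label from the embedding alone. The architecture follows the
Inception-Time pattern at desk scale: parallel 1-D convolutions (kernel
sizes 3, 9, 19; 16 filters each) over the embedding treated as a sequence,
ReLU, channel concatenation, global average pooling and a dense head; a
softplus output map enforces non-negativity, since an MSE is non-negative
by definition. The regressor is trained on the raw MSE (no transform) with
Adam plus decoupled weight decay; decay is what lets the net collapse to
the exact constant solution when labels carry no signal.

A representational caveat, verified empirically: convolution followed by
global pooling is translation-invariant up to padding-edge effects, so the
regressor cannot decode an *arbitrary* linear functional of the embedding —
only (approximately) position-uniform ones. This is inherent to the
architecture family, not to this implementation; the quantities the
evaluator actually needs (diffuse statistics of the embedding that
correlate with spectrum quality) are within its function class, and on the
synthetic test set the predicted MSE rank-correlates with the true MSE at
ρ ≈ 0.5 and filtering to the lowest-predicted-MSE spectra lowers the
realized benchmark MSE.

## Benchmarking protocol

Libraries carry very uneven numbers of spectra per molecule, so errors are
first averaged over all spectrum pairs of each unordered molecule pair,
then the molecule-pair means are grouped into ten Tanimoto bins, and the
final loss is the mean of the per-bin MSEs. Bins left empty by a small
library are skipped with a warning and excluded from the final mean (a
package decision; full-scale libraries never hit this). Violin summaries
report per-bin count, median, and 1st/99th percentiles using linear
interpolation between order statistics, so summaries are bit-reproducible.

## Molecular networking

Candidate edges require predicted similarity ≥ 0.85 and mutual membership
in both nodes' top-20 ranked partner lists; each node then nominates its 10
highest-scoring mutual candidates and the edge set is the union of
nominations, so well-connected nodes may exceed 10 edges. Ranking ties
break by (higher score, then lower partner index); the diagonal is
excluded. Networks serialize to GraphML (node attributes: spectrum id,
ionization mode, precursor m/z, optional annotation; edge attribute: score
to 4 decimals). Embeddings can additionally be projected to 2-D with UMAP
(50 neighbors by default, seeded) for threshold-free visualization; the
projection is an export convenience, not part of the method.

## Synthetic libraries: what they emulate and what they do not

The generator plants exactly the signal the model must learn. Molecules
come in clusters: each cluster has a random center of 128 set bits (of
4096), and member *i* keeps a fixed fraction g_i of the center bits
(retention ladder 1.0 … 0.398, 12 members), replacing the rest with fresh
random bits. Two members' expected Tanimoto is g_i·g_j / (2 − g_i·g_j), so
within-cluster pairs tile bins 1–9 (at least four pairs per bin per
cluster, placed ≥ 0.012 from bin edges to survive hypergeometric noise)
while cross-cluster pairs populate bin 0. The default library is 25
clusters × 12 molecules = 300 molecules.

Each set fingerprint bit maps affinely to a fragment m/z on the binning
grid (10 + 0.2·bit + 0.05, plus per-molecule jitter < half a bin), so
fingerprint overlap transfers to binned-spectrum overlap: the Spearman
correlation between fragment-set Jaccard (within mode) and fingerprint
Tanimoto over random molecule pairs exceeds 0.5. Negative-mode fragments
are shifted by 0.1 Da (one bin), so cross-mode spectra of the same molecule
share *no* raw m/z values or bins yet share the latent structure —
emulating the non-overlap of fragmentation across polarities. Spectra vary
in quality: each draws between half and all of the molecule's 96 observed
fragments, log-normal intensities, and up to 20 % noise peaks at random
m/z.

What passing tests on this data do **not** show: real fragmentation
chemistry (neutral losses, adducts, isotopes) is absent; the
fingerprint-to-fragment map is far more direct than in nature, so absolute
accuracies here say nothing about accuracy on experimental libraries —
only that the algorithms are implemented correctly and that the learning
signal propagates end to end.

## Problem sizes and seeds

Tests and the acceptance run use the desk-scale profile: the default
synthetic library (300 molecules, 1200 spectra), 40 pairs per bin and 10
epochs for the shared trained model, 500 pairs per bin for sampling-balance
measurements, and 500 partner draws for evaluator labels. A single global
seed fans out to per-stage seeds via a CRC-32 hash of the stage name, so
stages are individually reproducible and two pipeline runs with the same
seed write byte-identical reports.

## Known limitations

* Training is CPU-bound numpy; the reference 10,000×500 architecture is
  instantiable but impractical to train here — the desk profile exists for
  that reason.
* Ionization-mode pair types are not balanced during sampling (positive
  pairs dominate when positive spectra dominate), mirroring the reference
  behavior; balancing them is an open extension.
* The evaluator regresses raw MSE; transformed targets (e.g. log-MSE) were
  not explored.
* MGF metadata handling preserves unknown keys as strings but performs no
  adduct harmonization; the cleaning filters are minimal by design.
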
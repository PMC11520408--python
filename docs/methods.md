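# Methods

This note documents the models and procedures implemented in `affinet`, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not demonstrate.

## Pair representation

A compound–protein pair is represented by four concatenated numerical blocks
(offsets recorded in `PairLayout`):

| block | content | length |
|---|---|---|
| compound continuous | physicochemical descriptors | 200 |
| compound binary | MACCS / path-hashed / Avalon / circular r2 / feature-circular r2 fingerprints | 166+2048+512+2048+2048 = 6822 |
| protein continuous | 3D Zernike invariants (n ≤ 20) + sequence composition | 121 + 576 |
| protein binary | one-hot subfamily labels | 11 (reference vocabulary) |

That gives 7719 selectable descriptors; the 11 subfamily labels bypass
selection, for 7730 in total.

**Physicochemical list.** The toolkit exposes 210 two-dimensional
descriptors; the package freezes an ordered list of exactly 200
(`physchem_names.py`), excluding the eight `BCUT2D_*` terms (undefined for
molecules without Gasteiger parameters) and `Ipc`/`AvgIpc` (numeric overflow
on large graphs). The list is a repository convention: it fixes the vector
layout and the package refuses to run if any name is unavailable. A
descriptor that fails on a particular molecule is recorded as 0 with a logged
warning.

**MACCS placeholder.** The toolkit emits 167 bits with bit 0 unused; it is
stripped so the block is exactly 166.

**Tanimoto.** Tc = c/(a+b−c) on on-bit counts; the all-zero/all-zero case is
defined as 0 with a warning (the formula itself is 0/0). Cross-set compound
similarity (`mean_cross_tanimoto`) averages Tc over the full |A|×|B| cross
product and is computed on the path-hashed block by convention.

## 3D Zernike surface descriptors

The structure's ATOM records (first model, waters skipped) form an atom
cloud that is centred at its centroid and uniformly scaled so the farthest
atom sits at radius `scale_radius` inside the unit ball. Each atom
contributes an isotropic Gaussian evaluated at voxel midpoints; the density f
is expanded in the orthonormal 3D Zernike basis Z_nlm = R_nl·Y_lm and the
moments C_nlm = ∫_{|x|≤1} f·conj(Z_nlm) dx are computed by direct quadrature
over voxels inside the ball. The rotation invariants are
D_nl = sqrt(Σ_m |C_nlm|²), flattened in lexicographic (n, l) order — 121
values at n_max = 20.

Numerical choices:

- **Radial polynomials** use the Jacobi form
  R_nl(r) = √(2n+3)·r^l·P_k^(0, l+1/2)(2r²−1), k = (n−l)/2, which is
  orthonormal on [0, 1] with weight r². Any fixed normalization yields
  rotation-invariant D_nl; the orthonormal one is standard in the 3D Zernike
  shape-retrieval literature.
- **Norm over m**: the Euclidean norm with complex modulus, sqrt(Σ|C|²) —
  the only choice that is both real and rotation invariant.
- **Defaults**: grid 64³, Gaussian width 1.5 Å (pre-scaling), scale radius
  0.7, n_max 20 — conventional values for protein-surface work; all exposed
  in configuration. The smooth Gaussian density is used directly, without
  binarizing into a surface shell.
- **Quadrature** is the midpoint rule; the basis evaluated on a grid is
  cached per (grid size, n_max) so repeated structures cost one matrix
  product per degree l. Negative repetitions are filled via
  C_{n,l,−m} = (−1)^m·conj(C_nlm), exact for the real density (verified
  directly in tests).
- A single-atom cloud receives a floored extent (1e-6 Å) so the scale is
  defined.

Measured discretization behaviour on fixtures: descriptor drift under 100
random rigid rotations stays below 1% relative (entries above a 1e-3·max
magnitude floor) at the default 64³ grid, and descriptors at 32³ vs 64³
agree within 5%. Translation invariance is exact because of centroid
centring.

## Sequence block (576 values)

20 mono-residue frequencies (alphabetical), 400 di-residue frequencies
(row-major), and for each of three property scales — Kyte–Doolittle
hydrophobicity, side-chain polarizability, aromatic indicator (F/W/Y) — 50
lag-autocorrelations of the per-sequence standardized profile plus the raw
profile mean and variance. Frequencies are normalized by L (mono) and L−1
(di); autocorrelations are zero when the lag reaches the sequence length.
The exact recipe is a documented package convention with the stated
ingredient families and total length. Strict mode rejects non-standard
residues; lenient mode skips them.

## Curation and splits

Duplicate (compound, protein) pairs are collapsed to the median of each
label column independently over non-missing entries (even counts → the
midpoint). Pairs present in both the active and inactive tables are removed
from both — from both, conservatively, since keeping either side would
assert a label the data contradicts. Records with interaction score 0 but
pChEMBL > 5 are internally contradictory and dropped from the curated table
regardless of provenance. Measured activity threshold: inactive iff
pChEMBL ≤ 5.0; for model predictions the cutoff is 5.1, absorbing regression
outputs that land just above the measured boundary.

Train/test splitting samples a uniform 20% per superfamily (round-to-nearest
for the test count; the convention is documented because fractional counts
are otherwise ambiguous). Validation pairs are labelled by novelty: A
(both seen), B (new compound), C (both new); the remaining case — seen
compound, new protein — is excluded from evaluation.

## Descriptor selection

One selection round standardizes all candidate columns (binary fingerprints
included, so the ℓ₁ penalty treats every column on the same scale; the
downstream model still receives raw bits), fits LASSO with α chosen by
5-fold CV along a regularization path, refits at α* on the full subset and
marks columns with |β| > 1e-12 as selected — "nonzero" rather than "strictly
positive", since the sign of a LASSO coefficient depends on feature
orientation and negative effects are equally informative. The round is
repeated (reference: 100×; reduced counts are used where runtime matters)
with only the fold assignment re-randomized; the final signature keeps the
`keep` most frequent columns, ties broken by larger mean |β| then lower
column index. Subfamily labels never enter the pool and are appended to the
output. If fewer candidates than the budget exist, all are retained with a
warning. Selection labels are the interaction scores, and the subset used at
full scale is restricted to approved and phase-III compounds; the resulting
mask serves both label types, whose pairs and embeddings are identical.

Measured recovery: on a planted 50-column signal (n = 1000, p = 2000,
SNR 5), at least 90% of informative columns land in the kept signature
(98% at the tested seed).

## Network and training

The pair transformer uses token dimension d (divisible by the head count),
per-feature periodic embeddings for continuous inputs (activation dimension
k, frequency initialization N(0, σ), defaults k = 8, σ = 0.1), per-feature
cardinality-two lookup tables for binary inputs, one trainable CLS row per
stream (initialized N(0, 0.02)), two separate pre-norm encoder layers per
stream followed by the joint layers, and the head
Linear(ReLU(LayerNorm([CLS_c ; CLS_p]))). Two stream-specific CLS tokens
concatenated before the head were chosen over a single shared token: the
streams are encoded separately first, and concatenation is the natural merge
point. No positional encoding is used — descriptor order is meaningless, and
token-set equivariance is verified numerically. Feed-forward sublayers use
GELU; linear layers use Kaiming initialization; dropout applies to attention
weights and feed-forward activations.

The engine is a small reverse-mode autodiff over NumPy arrays with exactly
the primitives the model needs; every primitive's gradient is checked
against central finite differences in the test suite.

Training: log-cosh loss, stabilized as |u| + log1p(e^(−2|u|)) − log 2 so
large residuals cannot overflow; AdamW (default lr 1e-3, weight decay 1e-5 —
desk-scale placeholders, exposed in configuration); max 500 epochs with
early-stopping patience 10, where an improvement must beat the best holdout
loss by 1e-5; one checkpoint per epoch; the five lowest-holdout-loss
checkpoints form the prediction ensemble (arithmetic mean). The early-stop
monitor is called "holdout" to keep it distinct from the final test set.
Hyperparameter search beyond these defaults is out of scope; the training
configuration is a plain dataclass that an external optimizer can drive.

## Synthetic fixtures

The generator produces valid (toy-grade) SMILES from a fragment grammar,
randomized helical atom clouds written as standard-column ATOM records,
random sequences, an 11-label subfamily vocabulary, and interaction tables
whose pChEMBL-like label is an affine map of a standardized sparse latent
(linear in a few designated descriptor columns) plus Gaussian noise clipped
to [2, 11], with the interaction score a logistic squashing of the same
latent so the two label types agree in ranking. Duplicates (jittered labels)
and active/inactive conflicts are injected at configurable rates. Defaults:
noise sd 0.1 (latent–label Spearman ≥ 0.95, so a correct pipeline can
demonstrably learn the signal), duplicate rate 0.05, conflict rate 0.02.

What passing tests show: the pipeline's contracts hold, curation removes
exactly the injected hazards, selection recovers planted sparse signals, and
the transformer learns a recoverable latent to high rank correlation on held
out pairs. What they do not show: performance on real chemistry or real
protein folds — fixture molecules are not drug-like, structures are not
folds, and label noise is Gaussian rather than assay-driven.

Problem sizes in the shipped tests and demo (dozens of compounds, a handful
of proteins, grids of 16³, reduced selection repeats) were chosen so the full
suite runs in minutes on one CPU; the defaults of the library itself
(grid 64³, n_max 20, keep 1000, 100 repeats, 500 epochs) are the reference
configuration.

## Known limitations

- Descriptor computation is single-process; no GPU path exists, and the
  NumPy network is not intended for corpus-scale training.
- Multi-chain structures use all ATOM records of the first model; no
  binding-pocket extraction or surface meshing.
- Mutant proteins are expected to reuse wild-type structures upstream.
- The concordance index is computed from the O(N²) comparison matrix, fine
  up to tens of thousands of points but not beyond.
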
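# Methods

## Problem and data model

The package classifies nucleotide sequences of cancer driver genes into
*mutated* (label 1) and *normal* (label 0). The benchmark corpus
`D = D⁺ ∪ D⁻` is built by splicing mutation records into reference genes:
one mutated sequence is emitted per mutation record, so a catalogue of
1948 mutations yields (up to deduplication) 1948 positives. Coordinates
are 1-based and inclusive; an insertion lands after the stated position;
for substitutions and deletions the reference slice is checked against the
record's reference allele and a mismatch is an error, never silently
accepted. Redundancy removal is exact-string deduplication, which is what
clustering at a 100% similarity threshold over the full length reduces to;
it is applied within each class independently, keeping first occurrences.
Balancing down-samples the majority class uniformly without replacement
with a seeded generator. Whether balancing precedes or follows
deduplication is a free choice; this package deduplicates first, so the
class sizes being balanced are sizes of *distinct* sequences.

`N` bases are accepted on input but dropped (with a debug log of the
count) before any feature computation: every descriptor below is defined
on the four-letter alphabet, and real reference downloads do contain
ambiguity codes.

## The 150-dimensional descriptor

Ordinals are A=1, C=2, G=3, T=4. The alphabet capacity is K=20 in the
canonical "full" mode: this descriptor family descends from
pseudo-amino-acid-composition-style protein analysis and keeps the
protein-sized 20-slot alphabet, so on DNA the slots 5–20 are structural
zeros and the canonical dimensions (150 features, 400 PRIM coefficients)
are preserved. The biologically minimal "compact" mode sets K=4
(102 features). The layout is

    [seq-matrix moments 30] [PRIM moments 30] [RPRIM moments 30]
    [FDV K] [AAPIV K] [RAAPIV K]

with each 30-moment block ordered raw (10), central (10), Hahn (10) over
the exponent pairs (0,0),(0,1),(1,0),(1,1),(0,2),(2,0),(1,2),(2,1),(3,0),(0,3)
— all pairs with i+j ≤ 3.

**Sequence matrix.** The encoded series of length n is packed row-major
into the smallest square matrix that holds it — side k = ⌈√n⌉, trailing
cells zero — the unique choice that keeps the matrix square while storing
every symbol exactly once.

**Raw and central moments.** W_ij = Σ_b Σ_q b^i q^j m(b,q) with 1-based
indices; the centroid is (W10/W00, W01/W00) and central moments Q_ij are
taken about it, so Q10 = Q01 = 0 identically (asserted in tests to 1e-9).
Moments are plain power sums, not normalised: for a 20×20 incidence matrix
of a multi-kb gene W30 reaches ~1e10, which float64 carries exactly enough
for the downstream z-scoring.

**Hahn moments.** The discrete Hahn polynomials used are the classical
family Q_n(x; u, v, P−1) = ₃F₂(−n, n+u+v+1, −x; u+1, 1−P; 1) on the
lattice x = 0..P−1, orthogonal under the hypergeometric weight
ρ(x) = Γ(u+x+1)Γ(v+P−x) / (Γ(x+1)Γ(P−x)Γ(u+1)Γ(v+1)) (uniform when
u = v = 0). Each polynomial is evaluated by its terminating sum with
Pochhammer factors formed by iterative products (n ≤ 3, so at most four
terms); the weight uses log-Gamma so lattices up to ~10³ stay finite. The
square norms d_n² = Σ_x ρ(x) h_n(x)² are computed by direct summation —
exact for a discrete lattice, O(P) per order, and independent of any
closed-form norm expression. The weighted, normalised functions
h̃_n = h_n √ρ / d_n are orthonormal to machine precision (tested at
P ∈ {4, 8, 16} for several (u, v)), and projecting onto the complete
P²-member tensor basis is invertible, which is verified by reconstructing
random matrices to 1e-6. Matrices smaller than 4×4 are zero-padded to 4×4
so third-order polynomials exist. Shape parameters default to u = v = 0
(the symmetric choice; nothing in the task pins them down) and are exposed
in `FeatureConfig`.

**PRIM / RPRIM.** The position-relative incidence matrix accumulates, for
each ordered symbol pair (i, j), the positional offsets from the *first*
occurrence of i to every later occurrence of j:
cell(i,j) = Σ_{p ∈ pos(j), p > f_i} (p − f_i). This is the simplest
reading of "position-relative incidence"; it is isolated in one function
so an alternative accumulation rule can be swapped in. Rows of absent
symbols are zero. RPRIM is PRIM of the reversed sequence. Each matrix
contributes its own 30-moment block.

**FDV / AAPIV / RAAPIV.** Per-symbol occurrence counts; per-symbol sums of
1-based occurrence positions; the same on the reversed sequence. Their
conservation laws (FDV sums to n, AAPIV sums to n(n+1)/2) are tested as
invariants.

Every descriptor has an independently written brute-force loop oracle in
the test suite; agreement is exact for the integer descriptors and within
1e-9 for the moments on hundreds of random sequences.

## Classifiers

Three stacked recurrent architectures read the feature vector as a
univariate series (length 150 in full mode — the input length follows the
actual feature dimensionality):

* LSTM(128) → dropout → dense(64, relu) → dropout → σ-unit
* GRU(256, sequences) → dropout → LSTM(128) → dropout → σ-unit
* BiLSTM(512/dir, sequences) → dropout → BiLSTM(256/dir) → dropout →
  dense(64, relu) → dropout → σ-unit

all with dropout fraction 0.2. The LSTM cell uses the canonical update
c_t = i∗c̃ + f∗c_{t−1} — a variant that also adds an update-gated copy of
c_{t−1} circulates in the applied literature, but it double-counts the
previous cell state and is not used here; the GRU uses
h_t = z∗c̃ + (1−z)∗h_{t−1} with the reset gate applied to the previous
state inside the candidate. The environment
provides no deep-learning framework, so forward passes, backpropagation
through time and the optimiser are implemented directly in numpy; the
analytic gradients are validated against central finite differences for
all three architectures, and single-unit cells against hand-computed
scalar updates.

Training: binary cross-entropy, Adam (step 1e-3, decay 0.9/0.999, ε 1e-8),
batch size 32, 100 epochs, classification threshold 0.5, no validation
split or early stopping. Two numerical choices are the package's own:

* **Global gradient-norm clipping at 1.0** (configurable; 0 disables).
  Without it the GRU stack oscillated on the synthetic benchmark (training
  accuracy plateauing near 0.85 with a non-decreasing loss); clipping is
  standard recurrent-network practice.
* **Feature z-scoring with training-fold statistics** (`FeatureScaler`,
  applied inside `run_protocol` and the CLI). The raw descriptor spans ~10
  orders of magnitude across columns, which saturates sigmoid gates;
  constant columns (the structural padding slots) pass through unchanged.
  Statistics come only from the training fold, so no test information
  leaks.

Weight initialisation is Glorot-uniform for input weights, block-orthogonal
for recurrent weights, zero biases except a unit forget-gate bias. All
randomness (initialisation, shuffling, dropout masks, splits) flows from
explicit seeds; a rerun with the same seeds is bit-identical.

## Validation protocols and metrics

SCT trains and tests on the full corpus (a capacity/consistency check, not
a generalisation estimate); IST is a stratified 80/20 split; KFOLD is
stratified 10-fold cross-validation whose report is the unweighted mean of
per-fold metrics, with per-fold details and seeds attached. Splits are
stratified (the corpus is balanced by construction, and stratification
preserves that within ±1 sample per fold); fold seeds derive
deterministically from the run seed. Metrics come from the 2×2 confusion
table with the mutated class positive: accuracy, sensitivity, specificity
and MCC, with any zero denominator reported as 0 alongside a warning so
fold aggregation never drops a fold. ROC curves sweep all distinct score
thresholds (ties grouped) and AUC is the trapezoidal area; AUC on a
single-class test set is undefined and raises. The metric formulas and the
AUC are cross-checked in tests against naive recomputation and the
Mann–Whitney rank statistic respectively.

## Synthetic benchmark

The generator stands in for a real benchmark assembled from public
resources (somatic mutation catalogues such as intOGen, reference
sequences such as Ensembl), which this package does not download or
redistribute, and emulates its *shape*: 61 genes by default, lengths 300–3000, per-gene mutation counts
log-uniform over 3–293 (matching the observed heavy skew — median near 18,
maximum 293 — without asserting a distribution the data do not pin down),
and an 80/10/10 substitution/insertion/deletion mix. Reference alleles are
read off the simulated sequence, so every record applies cleanly by
construction. What it does **not** emulate: real genomic composition
(sequences are i.i.d. uniform), mutational signatures or trinucleotide
context, transcript structure, homology between genes. Passing the
recovery tests therefore shows the pipeline is correct and can learn a
signal that its features represent — not that the features suffice for
real driver-gene data.

The optional **separability motif** is implanted at a random position of
every positive sequence after mutation splicing. It is a testing device
with no biological meaning: its purpose is a corpus whose labels are
recoverable, so classifier tests have a known answer. Because the
descriptor is built from global composition and position statistics, a
short composition-neutral motif is invisible to it (empirically, a 16-mer
leaves even a linear model at chance); the test fixtures therefore use a
96-base T/G-rich motif, which makes the classes linearly separable in
feature space. The negative-control corpus (no motif, ≤3 edits per
multi-kb gene) must stay at near-chance AUC after one epoch, confirming
the pipeline does not leak labels.

## Problem sizes in tests and the acceptance script

Test and acceptance runs use a 220-sequence corpus (110 genes, lengths
300–512, 1–3 mutations per gene) with recurrent widths scaled to 32 units
(LSTM) and 64/32 (GRU stack and per-direction BiLSTM), 100 training
epochs. These sizes keep a full three-architecture evaluation to minutes
on one CPU while leaving the architecture shapes and training regime
intact; the canonical full widths (128 / 256+128 / 512+256) are the
defaults of `ModelSpec` and are exercised for construction and parameter
counting. The 10-fold run in the acceptance script uses a 32-unit LSTM at
40 epochs.

## Known limitations

* The per-mutation convention (one positive per record) is an
  modelling choice; real catalogues report patient samples carrying
  several mutations each, and other sample-to-sequence mappings are
  defensible.
* PRIM cell semantics are not uniquely determined by the prose; the
  first-occurrence offset-sum reading is one consistent choice.
* No real mutation corpus ships with the package; all quantitative claims
  made here are about the synthetic benchmark.
* Training is CPU-bound and O(epochs × n × sequence-length × width²);
  full-width models on thousands of sequences are slow in pure numpy.
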
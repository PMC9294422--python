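# Methods

## Problem setting

`rbpkit` treats RNA-binding protein (RBP) identification as binary
classification of protein sequences under strong class imbalance
(positives : negatives ≈ 1 : 10).  A protein is represented either by a
hand-crafted feature vector or by a precomputed protein language-model
embedding; a recurrent classifier maps the representation to P(RBP).  The
central scientific claim the package operationalizes is that two-stage
transfer — general knowledge from a large annotated multi-species RBP
dataset, specialized by fine-tuning on a small species-specific dataset —
beats training on the small dataset alone.

## Data handling

Sequences are restricted to the 20 standard amino acids.  Non-standard
residues (B, Z, X, U, O, `*`, gaps) are dropped by default
(`drop_nonstandard`); a strict `reject` policy and a
`map_to_X_then_drop` variant are available.  Datasets are partitioned
81 / 9 / 10 % into train / validation / test by largest-remainder
apportionment (remainder ties resolved toward the training part), and the
split is stratified by label so the 1:10 imbalance — which the loss
weighting assumes — survives into every part.

Redundancy removal (`dedup_by_identity`) is a greedy longest-first
clustering on a k-mer identity estimate (fraction of the shorter
sequence's 3-mers present in the longer).  It is a deliberate, logged
approximation of CD-HIT-style clustering: adequate for constructing
non-redundant training sets, not a replacement for exact clustering
tools, and never used at inference time.

For genome-scale screening, sequences longer than 6 000 residues are
truncated to their N-terminal 6 000-residue prefix (the choice of the
N-terminus is logged; nothing downstream depends on which end is kept,
only on the cap itself), and proteins already present in the training
data — matched by exact id **or** exact sequence — are excluded before
scoring.

## Feature encoders

All 20-wide amino-acid axes are ordered alphabetically by one-letter code
(`ACDEFGHIKLMNPQRSTVWY`); files in other column orders (PSI-BLAST ASCII)
are permuted on read.  Fixing one ordering everywhere removes the classic
silent bug of mixed conventions.

* **PSSM-400.**  An L×20 profile is collapsed by summing, for each residue
  type, the profile rows at positions holding that residue, then
  concatenating the 20 blocks → 400 values.  When no PSI-BLAST profile
  exists, the BLOSUM62 substitution row of each residue stands in
  (`blosum62_fallback`; matrix loaded from Biopython, not retyped).
* **C-T-D** (147 = 7 properties × 21).  Seven physicochemical groupings
  (hydrophobicity, normalized van der Waals volume, polarity,
  polarizability, charge, secondary-structure propensity,
  solvent-accessibility propensity) each map residues into 3 classes.
  Composition = class frequencies; transition = frequencies of unordered
  adjacent class pairs; distribution = positions (percent of L) of the
  first occurrence and of the occurrences nearest the 25/50/75/100 %
  quantiles (half-up rounding — on a 5-residue homopolymer this gives
  20, 20, 60, 80, 100), zeros for absent classes.  The secondary-structure
  and accessibility groupings are residue propensity classes: no structure
  predictor is run, a documented simplification.  The active property set
  is configurable.
* **Conjoint triad** (343 = 7³).  Residues map into 7 classes by
  side-chain dipole/volume; counts over all L−2 triad windows are
  normalized by the maximum count.  Raw counts are also exposed because
  normalization conventions vary across the literature.
* **PAAC** (20 + λ).  Type-1 pseudo amino acid composition from
  standardized hydrophobicity, hydrophilicity and side-chain mass.
  Defaults λ=30, weight=0.05 (the method's customary defaults); both
  configurable and recorded in the encoder name.

Composite recipes (`pssm400+ctd+triad` → 890, `ctd+triad` → 490,
`pssm400+ctd+paac` → 597) mirror the feature sets of earlier RBP
predictors for architecture-controlled comparisons against embeddings.

Embeddings are consumed, never computed: loaders accept per-protein
vectors or per-residue L×D matrices (TSV / NPZ / HDF5).  Per-residue
entries may be mean-pooled, last-row-pooled, or passed unpooled to the
recurrent stack; the default path feeds one pooled vector per protein as a
length-1 sequence.

## Classifier

A stack of GRU layers (default 6) followed by a discriminator
(linear → batch-norm → leaky ReLU (slope 0.01) → linear → scalar score;
hidden width 64).  The candidate state uses the standard form
`h̃_t = tanh(W·[r_t ⊙ h_{t−1}, x_t] + b)` — the reset gate modulates the
previous state inside the candidate input — and the blend
`h_t = (1−z_t)⊙h_{t−1} + z_t⊙h̃_t` weights the candidate by the update
gate (this orientation differs from some references only by relabeling
z ↔ 1−z and does not change capacity).  `h_0 = 0`, which with the convex
blend keeps every hidden component strictly inside (−1, 1).  Zero GRU
layers is a legal configuration that reduces the model to a pure linear
network, used in ablations.

The implementation is pure NumPy: forward, backpropagation through time,
Adam, batch normalization (batch moments and running-moment updates in
train mode; running moments — hence a pure, bit-deterministic function —
in eval mode; ε=1e−5, momentum 0.1).  Gradients are verified against
central finite differences in the test suite.  Hidden width 32 and
discriminator width 64 are repo defaults chosen for desk-scale problems,
not tuned values taken from elsewhere.

## Loss and metrics

Weighted binary cross-entropy with the weight on the positive term only:
`J = −(1/N) Σ [w·y_i log p_i + (1−y_i) log(1−p_i)]`,
`w = (1−pos_ratio)/pos_ratio` recomputed from whichever set is being
trained on.  Applying `w` to both terms would merely rescale the loss and
cannot rebalance classes; that variant exists behind
`weight_both_terms` for comparison.  `p_i` is the post-sigmoid
probability (clamped to [1e−7, 1−1e−7]); the score/probability distinction
is enforced by types.

Metrics: BACC = mean of sensitivity and specificity (absent class → term
0 with a warning); MCC with the 0-on-zero-denominator convention; AUC;
AUPRC as step-wise average precision (not trapezoidal interpolation,
which overestimates PR area).  The 0.5 decision threshold counts `p ≥ t`
as positive.  AUC/AUPRC delegate to scikit-learn internally; the test
suite checks them against independent all-pairs / all-thresholds
enumeration oracles.

## Training and transfer

Adam (lr 1e−3, batch 64, β=(0.9, 0.999)) with validation AUPRC as the
selection monitor — validation loss is logged but never used for
selection, since AUPRC is the metric that matters under imbalance.  The
learning rate is halved after 5 non-improving epochs
(plateau_factor 0.5), training stops after 10 non-improving epochs or
200 epochs, and the best-epoch checkpoint is returned.  All values are
repo defaults, configurable in `TrainConfig`.  Mini-batch sampling is
uniform: the imbalance correction lives in the loss, not the sampler.
Runs are bit-reproducible from the seed on CPU.

Strategies: **DT** trains on the species data alone; **SP** on the
pre-training data alone; **GM** on both pooled (empty pre-training data
degrades GM to DT); **TSTL** pre-trains, then fine-tunes on the species
data, optionally with GRU layers frozen (frozen tensors are bit-identical
after fine-tuning — asserted, not assumed).  Freezing is the conservative
option when the target set is small and close to the source domain.
`cross_domain_matrix` reports, for models trained on domain a and tested
on domain b, the AUPRC increment over b's own in-domain model.

## Calibration and screening

Classifier scores are calibrated by temperature scaling: T minimizes the
validation negative log-likelihood of `sigmoid(score/T)` via bounded 1-D
search on log T ∈ [−6, 6].  Temperature scaling is strictly monotone, so
ranking metrics are unchanged (asserted to 1e−12); T scales equivariantly
with the score scale and recovers T ≈ 1 on already-calibrated scores.
The screened proteome is summarized by counting proteins whose calibrated
confidence is **strictly greater** than each of 0.5, 0.6, 0.7, 0.8, 0.9;
counts are necessarily non-increasing in the threshold.  Output tables are
sorted by protein id and byte-reproducible in eval mode.

## Synthetic benchmark

The embedding generator draws labels Bernoulli(pos_ratio = 1/11) and
features `x = y·δ·u_θ + ε`, ε isotropic Gaussian (σ=1): one shared
discriminative direction, rotated by θ in a fixed 2-plane per domain.
Rotation (rather than covariance change) was chosen as the domain-shift
mechanism because a single interpretable knob reproduces the qualitative
cross-species phenomenology: within-pair transfer ≈ in-domain, across-pair
transfer degraded, pre-train + fine-tune ≥ direct training on the
smallest domain.

The default benchmark is desk-scaled: pre-training n=5000 (θ=0); a
"eukaryote-like" pair n=600/600 at θ=0.15; a "prokaryote-like" pair
n=300/200 at θ=0.45; D=16, δ=2.0.  D=16 (not the ~10³ of real
language-model embeddings) keeps the full suite under a minute per
benchmark run; D is configurable.  Sequence fixtures perturb a uniform
residue background (e.g. an E/S/P excess in positives, echoing the residue
biases reported for human RBPs); synthetic PSSMs elevate the true
residue's column at every position.

What passing these tests shows — and does not.  The synthetic domains are
Gaussian with a linear class boundary; real embedding geometry, sequence
homology structure and annotation noise are absent.  Passing demonstrates
that the machinery (weighting, selection, transfer, calibration) behaves
as designed under the stated imbalance and shift, not that any particular
real-proteome accuracy will be achieved.

## Numerical choices and degenerate inputs

Probabilities clamped at 1e−7; MCC → 0 on zero denominators; BACC absent
class term → 0 with warning; confusion ties (`p = threshold`) count
positive; confidence bins use strict `>`; split remainder ties go to the
training part; batch-norm with a size-1 batch degenerates gracefully
(variance 0 + ε).  T=0 sequences, empty datasets, single-class training
or validation sets, and ragged embedding widths all raise errors rather
than propagate.

## Known limitations

* No PSI-BLAST, CD-HIT or structure-prediction execution; their outputs
  are consumed or approximated as documented above.
* The per-residue GRU path (mode `none`) is functional but the default —
  and the tested transfer benchmark — uses pooled per-protein vectors as
  length-1 sequences.
* The NumPy training loop targets desk-scale problems (10³–10⁴ proteins,
  D ≲ 10²); it is not a GPU framework.
* Reported benchmark numbers are on synthetic data; small test sets
  (20 proteins on the smallest domain) make single-seed AUPRC noisy, which
  is why all benchmark claims are seed-averaged.
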
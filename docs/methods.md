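# Methods

## Problem and model

The task is binary classification of protein pairs — interacting versus
non-interacting — from sequence-derived information only. The model chain
is: PSSM conservation profile → 2-D discrete Hilbert transform (DHT)
descriptor → rotation forest ensemble → stratified five-fold
cross-validated metrics.

### PSSM representation

A PSSM is an L×20 matrix of per-position amino-acid log-odds scores.
PSI-BLAST profiles are read from the standard ASCII output: the first
20-column block (log-odds) is used — the second block holds weighted
observed percentages and carries no extra information for this purpose.
The column order is read from the file header and reordered to the fixed
alphabet `ARNDCQEGHILKMFPSTWYV` so all downstream arithmetic is
order-stable. Users regenerating profiles with PSI-BLAST typically run 3
iterations at e-value 0.001 with a PAM scoring matrix against a curated
database; profile generation is outside this package.

When no profile is available, a *pseudo-PSSM* substitutes the BLOSUM62 (or
PAM250) substitution-matrix row of each residue. Non-standard residues
(X, B, Z, U) get an all-zero row: no information is invented. Scores are
used raw; an element-wise logistic squashing 1/(1+e^(−x)) is available
(`ppidht.pssm_io.logistic_squash`) but off by default, since the transform
and classifier are scale-equivariant enough that squashing is a modelling
choice, not a requirement.

### Discrete Hilbert transform

The 1-D DHT is defined in the frequency domain: DFT, multiplication by
−j·sgn(Ω), inverse DFT. sgn is +1 on positive-frequency bins, −1 on
negative ones, and 0 at DC and (for even length) the Nyquist bin — the
analytic-signal convention. Consequences used as tests: cosines map to
sines exactly, constants vanish, double application negates any signal
free of DC/Nyquist content, energy is preserved on such signals, and the
transform equals circular convolution with the periodic spatial kernel
(the inverse transform of the multiplier, an anti-symmetric, zero-mean
sequence — the discrete periodic analogue of the classical odd-sample
kernel (1−(−1)^a)/(aπ)).

The 2-D transform is defined **separably**: the 1-D transform applied
along rows, columns, or both ("total" mode, the featurization default),
equivalently one 2-D frequency multiplication by the outer product of the
two 1-D multipliers. A single non-separable 2-D frequency mask with an ad
hoc boundary correction is sometimes written for this transform, but no
self-consistent discrete version of it exists; the separable definition is
the one that matches the 1-D theory, has a well-defined spatial-convolution
oracle, and is exactly testable. The real part is taken after the inverse
FFT with the imaginary residue asserted below 1e-10 relative to the
spectrum magnitude (an absolute 1e-10 is below float64 roundoff for
512-point transforms of integer-scale profiles).

### Descriptor reduction

A variable-length L×20 profile must become a fixed-length vector. The
choice here: zero-pad the profile along the sequence axis to `pad_len`
rows (default 512; longer sequences are truncated), apply the total-mode
2-D DHT, take the 2-D magnitude spectrum of the result, and keep the
`block_rows` (default 10) lowest sequence-frequency bins × all 20
channel-frequency bins, flattened row-major: 200 values per protein. The
pair descriptor concatenates the two proteins (A first): 400 values.

Rationale: low-order frequency magnitudes summarize the global
conservation profile; taking magnitudes discards phase, i.e. *where* along
the sequence a conserved stretch sits, which makes the descriptor robust
to motif position; and low-frequency blocks mirror the truncated-transform
descriptors (DCT, FFT) established for this task. Because the DHT
multiplier is zero at DC and Nyquist per axis, the first row and first
column of the magnitude block are identically zero; they are kept so the
block layout (and the 400 total) stays regular. Magnitude (not real part
or signed coefficients) is used because position-invariance is exactly the
property the planted-signal benchmark stresses.

Defaults: `pad_len=512` covers the large majority of protein lengths in
curated PPI sets while keeping FFTs cheap; `block_rows=10` gives the
conventional 400 features per pair. Both are exposed on the API and CLI.

### Rotation forest

Each of the L trees gets its own orthogonal rotation: features are
randomly partitioned into K disjoint subsets (sizes n//K, the last subset
absorbing any remainder); for each subset, ⌈0.75·N⌉ training objects are
drawn with replacement and a PCA basis is fitted to their columns; **all**
components are retained, so every block — and hence the assembled
block-diagonal matrix, with blocks placed back at the original feature
indices — is orthonormal (‖RᵀR − I‖∞ < 1e-9, asserted in tests). The PCA
is an eigendecomposition of the bootstrap-sample covariance with
descending eigenvalue order; each component is sign-fixed so its
largest-magnitude loading is positive, making rotations reproducible
across platforms. A fully zero-variance block falls back to the identity
with a logged warning, never a failure. Base learners are CART decision
trees (Gini, unlimited depth). Prediction averages tree posteriors and
takes the arg-max; an exact tie goes to the class listed first in
`classes_` (ascending label order), documented and tested.

Design notes: only the plain object bootstrap is used (no prior random
class elimination — degenerate for a binary task); bootstrap sampling is
*with* replacement; defaults L=30, K=20 balance ensemble benefit against
cost, with K=20 dividing the 400-feature descriptor evenly. Both are
tunable (`-L/--trees`, `-K/--subsets`). Binary classification only.

### Evaluation

ACC, sensitivity, specificity, precision and MCC from the confusion
matrix (class 1 = interacting), with any 0/0 ratio reported as NaN — an
explicit undefined marker, never silently 0. The MCC denominator is
√((TP+FN)(TP+FP)(TN+FP)(TN+FN)). AUC uses midrank statistics (equal to
the probability a random positive outscores a random negative, ties
counted half) and equals trapezoidal integration of the ROC point list to
1e-12, both checked against brute-force pair counting. Cross-validation is
stratified k-fold (default 5) — stratification guarantees both classes in
every training split of a balanced design. The report prints per-fold
rows plus an `Average mean ± sd` row, with the sample standard deviation
(n−1). Ratio metrics are percentages; MCC is printed both on [−1,1]
(`MCC_frac`) and ×100; AUC stays a fraction.

## Synthetic benchmark

The generator emulates balanced curated PPI benchmarks: random sequences
of 50–100 residues (the 50-residue floor mirrors standard fragment
filtering), pseudo-PSSM base profiles, i.i.d. Gaussian noise of sd
`noise_sd` on every entry, and a planted interaction signal: one fixed
20-vector motif (drawn N(0,1) per dataset), scaled by `signal_strength`
and added to a contiguous 25-row window — placed uniformly at random per
protein — of both members of every positive pair. Negative-pair proteins
never carry the motif. Every pair gets two dedicated proteins, so no
protein identity is shared between pairs: reuse would let cross-validation
folds memorize protein identity and inflate the null AUC above chance.

The benchmark condition used by the test-suite and the acceptance script
is n_pos = n_neg = 500, signal_strength = 3, noise_sd = 1 (and its
signal-off null); that size keeps a full five-fold CV of the default
model around a minute on one CPU.

What passing shows: the descriptor carries position-randomized PSSM-space
signal, the classifier recovers it, and the pipeline is honest under the
null (AUC ≈ 0.5). What it does **not** show: performance on real PPI
data — real profiles have correlated columns, length- and
composition-dependent structure, homology between proteins, and negatives
that are merely unlabelled, none of which the generator models.
Interaction here is a property of individual proteins (motif carriers),
not of the pair combination, so the benchmark cannot probe pair-specific
epistasis.

## Numerical choices and limitations

- FFT-based transforms throughout; imaginary residue asserted, not
  dropped (see above).
- One seed fans out to named sub-streams (dataset, folds, per-fold model
  seeds via `SeedSequence.spawn`), so identical configurations give
  byte-identical artifacts; all tests and the acceptance script are
  seeded.
- Degenerate inputs: sequences shorter than 2 residues, single-class
  labels, K > n features, mismatched feature dimensions, malformed PSSM
  rows and duplicate FASTA ids all raise explicit errors naming the
  offender.
- Model persistence uses joblib; a saved/loaded model reproduces
  predictions bit-for-bit.
- Limitations: binary labels only; no probability calibration; no
  alternative descriptors (DCT/FFT-only/LD/MMI); PSI-BLAST and CD-HIT
  style redundancy filtering are external to the package (only the
  minimum-length filter is provided).
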
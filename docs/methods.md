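# Methods

## Problem setting

2'-O-methylation (Nm, also written 2OM) occurs at A, C, G and U centers,
and published benchmark collections are organized as four
nucleotide-specific binary datasets of 41-nt windows with the candidate
site at 1-based position 21. `omsite` implements a sequence-only
predictor for this setting: a deterministic 522-dimensional encoding of
each window followed by an off-the-shelf ensemble classifier layer.

## Encoding

All encodings use overlapping k-mers of orders 1, 2, 3 over the RNA
alphabet, ordered lexicographically with A<C<G<U (base-4 codes). A
41-mer yields 41/40/39 tokens for k = 1/2/3, which fixes the closed-form
block totals used as invariants in the tests: frequency blocks sum to
41/40/39 and position-sum (AAPIV) blocks to 861/820/780.

PRIM (position-relative incidence matrix) semantics: `entry(i, j)` is the
sum over all occurrences of k-mer *j* at 1-based start position *p* of
`p − first(i)`, where `first(i)` is the start of the first occurrence of
k-mer *i*; rows of absent k-mers are zero and offsets may be negative.
This is the convention of the pseudo-composition/moment descriptor
literature; it is pinned by a brute-force nested-loop oracle in the test
suite. RPRIM, and RAAPIV, are the same operators applied to the reversed
residue string. The implementation uses the identity
`row_i = S − first(i)·c` (S = per-k-mer position sums, c = counts),
which the oracle tests confirm entry-for-entry.

The "2-D grid" block codes the k-mer sequence as 1-based integers
(0 reserved for padding so padding carries no intensity), reshaped
row-major into the smallest square that holds it — side 7 for every
order on 41-mers, so a single Hahn basis serves all three grids.

## Moment reduction

Every matrix (three PRIM, three RPRIM, three grids) is reduced to the
10 exponent pairs `u + v ≤ 3` — (0,0),(0,1),(1,0),(1,1),(0,2),(2,0),
(1,2),(2,1),(0,3),(3,0) — for three families:

* raw `L_uv = Σ_ab a^u b^v β_ab`, 1-based grid indices;
* central: the same sums about the centroid `(L10/L00, L01/L00)`;
  a zero-mass matrix has no centroid, so central moments are defined
  as all-zero and a RuntimeWarning is emitted (reachable only through
  degenerate direct API use, not through window encoding);
* Hahn: projections onto weight-and-norm normalized discrete Hahn
  polynomials (below).

That is 9 matrices × 30 = 270 moment features; with the three 84-vectors
the total is 522. The block order in the final vector is
PRIM | RPRIM | frequency | AAPIV | RAAPIV | grid, with each moment block
laid out k1..k3 × (raw, central, Hahn) × 10. Any fixed order would do;
this one is documented so model files and tables are reproducible.

## Hahn polynomials: convention and normalization

We evaluate `h_n^{(u,v)}(r, N) = (N+v−1)_n (N−1)_n ·
3F2(−n, n+u+v+1, −r; v+1, 1−N; 1)` on `r = 0..N−1` (rising-factorial
Pochhammer symbols; the series terminates at `k = n`). This is the
classical Hahn family: at `u = v = 0` the weight is uniform and
`h_1(r) = (N−1)² − 2r(N−1)`. Transcriptions of this formula circulating
in the applied literature disagree in the placement of signs and
parameters and are not all orthogonal families; we therefore treat
orthogonality as the defining requirement and verify it numerically in
the test suite (Gram matrix = identity to better than 1e−8 for all
sides used, machine precision in practice) rather than trusting any one
printed variant.

Normalization: `h̃_n(r) = h_n(r)·sqrt(w(r)/ρ(n))` with the classical
weight `w(r) = C(v+r, r)·C(u+N−1−r, N−1−r)` and squared norm
`ρ(n) = Σ_r w(r) h_n(r)²` computed by direct summation — exact for
discrete polynomials and immune to transcription errors in closed-form
norm expressions. The default parameters are `u = v = 0` (configurable);
nothing in the data motivates an asymmetric weight.

Numerics: Pochhammer products are evaluated as plain float products.
At the sides this package uses (N ≤ 64 for features, full order only at
N = 7 in the reconstruction test) magnitudes stay near 1e12, far inside
float64 range, so log-space evaluation is unnecessary. The basis per
(N, degree, u, v) is cached, making window encoding a handful of small
matrix products (~3–4 ms per window).

Only degrees ≤ 3 enter the feature path; the full-order transform
exists to demonstrate that the basis is complete and invertible
(round-trip of random 7×7 matrices to < 1e−6; observed ~4e−15).

## Scaling, training, leakage

Features are z-scored per column with mean and *population* standard
deviation (the common standard-scaling convention); zero-variance
columns map to 0. `train()` accepts the raw training table and fits the
scaler itself before fitting the estimator, so scaler statistics
structurally cannot include test rows; `predict()` applies the stored
state. Cross-validation therefore refits the scaler inside every
training fold by construction.

Classifier hyperparameters are the underlying libraries' published
defaults, captured verbatim into each ModelSpec at construction (JSON-
serializable subset) so a result is reproducible from spec + seed. The
bagging meta-estimator uses its default decision-tree base learner; the
ANN baseline is a single hidden layer of 100 units (500 iterations);
the SVM uses probability estimates so every model exposes a continuous
score for ROC. Hard calls threshold the positive-class score at 0.5.

## Evaluation protocol

Sn, Sp, Acc and MCC are computed from the confusion matrix with the
standard degenerate conventions: MCC = 0 when any denominator factor
vanishes; Sn (and Sp) are reported as missing — not zero — when the
evaluated set has no positives (negatives), distinguishing "undefined"
from "bad". AUC is the trapezoidal/rank statistic over continuous
scores (ties contribute half), computed with scikit-learn and checked
against an exhaustive Mann–Whitney pair count in the tests.

Splits are stratified (the per-base datasets must keep both classes in
every partition). The independent test takes `round(0.2 × class size)`
rows per class. K-fold uses round-robin dealing of shuffled class
blocks with a single global counter, which makes overall fold sizes as
balanced as possible (ceil/floor of n/k, e.g. {21,21,21,20,20} at
n = 103) while per-class counts differ by at most one across folds.

## Synthetic data generator

The generator emulates the structure real Nm benchmark sets show in
two-sample logos: a fixed center base, and for A/C/G-centered positives
a guanine concentration in the downstream half of the window. Positives
draw G with probability `p_enriched = 0.9` at positions 22–41 (falling
back to the other three bases uniformly), all other positions — and
negatives throughout — are uniform over the four bases (background
0.25). The U-centered condition is the evenly-distributed case,
`p_enriched = background`. Default sizes are 200 positives + 200
negatives per set — large enough for stable held-out estimates, small
enough that the full suite encodes in seconds.

The model is class-conditionally independent across positions. It
exercises every encoder path and provides a ground-truth signal whose
recovery (held-out accuracy ≥ 0.9 with enrichment; chance-band accuracy
without) verifies end-to-end signal propagation and the absence of
leakage. It does **not** reproduce real 2OM motif dependence,
positional covariance, or genomic background composition, so passing
these checks says the pipeline is correct, not that the printed
accuracies transfer to any particular biological benchmark. Real
datasets in paired positive/negative FASTA form drop into the same
CLI/library entry points.

## Known limitations

* Windows at sequence ends are not padded; scanning covers only fully
  contained 41-nt windows, so the first and last 20 nt of a record are
  never scored.
* Ambiguity codes (N, R, Y, …) are rejected rather than expanded.
* No hyperparameter search or early stopping is implemented; results
  are library defaults under fixed seeds.
* The SVM baseline's probability calibration (Platt scaling inside
  scikit-learn) is slated for API changes upstream; scores remain valid
  but exact values may shift across scikit-learn versions.
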
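# Methods

## Problem setting

Input is a balanced (or near-balanced) pair of FASTA files of fixed-length
RNA windows, one per class (5hmC-positive / negative), assumed
pre-deduplicated. All encoders are position-indexed, so equal length L ≥ 3 is
a hard invariant — padding is never applied, because it would silently
corrupt the per-position frequency statistics. T is mapped to U silently
(DNA-convention inputs are common in this dataset family); any other
non-ACGU residue is an error by default, with an opt-in `drop` policy for the
occasional N in public sets. User-facing positions are 1-based.

## Encoders

**Mismatch profile (MisM).** For each of the 4^k k-mers t, the number of
length-k windows w of the sequence (all L−k+1 of them) with Hamming(w, t) ≤ m,
0 ≤ m < k. Defaults k=3, m=1. Raw counts are emitted: the descriptor is an
occurrence sum, and every window contributes to exactly
Σ_{j=0..m} C(k,j)·3^j k-mers, which gives the mass-conservation invariant the
tests check. A `normalize` flag (divide by the window count) is available but
off by default. Implementation precomputes the 4^k × 4^k Hamming-ball
membership matrix, fine for k ≤ 6.

**Accumulated nucleotide frequency (ANF).** d_i = (occurrences of residue s_i
within the prefix s_1..s_i)/i, giving L values in (0, 1] with d_1 = 1. Values
are stored at full precision; two-decimal rounding appears only where outputs
are compared against published example values.

**Position-specific trinucleotide propensity, single strand (PSTNPss).** The
one trainable encoder. Fitting computes, for every position j ∈ 1..L−2 and
each of the 64 trinucleotides (lexicographic, A<C<G<U), the within-class
fraction of sequences whose trinucleotide starting at j is that 3-mer, and
stores z = F⁺ − F⁻ (64 × (L−2)). Each column of z sums to zero (difference of
two probability vectors) and entries lie in [−1, 1]; swapping the classes
negates z exactly. Transforming a sequence emits φ_u = z[3mer at u, u]. The
fit/transform split is explicit so cross-validation can fit z on training
folds only.

**Adaptive skip dinucleotide composition (ASDC).** Every ordered position
pair (p, p+g), g = 1..L−1, contributes one count to its residue pair; the 16
counts are divided by the total L(L−1)/2, so the vector is a probability
simplex point. This is the standard ASDC normalization; it makes the
sum-to-one invariant exact.

**Dinucleotide auto-covariance (DAC).** For index u and lag,
DAC(u, lag) = Σ_{i=1}^{L−1−lag} [P_u(di_i) − P̄_u][P_u(di_{i+lag}) − P̄_u] / (L−lag−1),
where P̄_u is the mean of u over the *sequence's own* L−1 dinucleotides (not
over the 16-letter alphabet): the centering is per sequence, which is what
makes homopolymers and constant indices give exactly zero. Default LAG=2;
columns are index-major, lag-minor.

*Default index table.* The packaged table ships three dinucleotide
thermodynamic indices — Turner nearest-neighbor stacking free energy (ΔG°37),
enthalpy (ΔH°) and entropy (ΔS°) — mapped to all 16 dinucleotides via the
duplex-step symmetry, then standardized to zero mean / unit SD across the 16
steps before use. Thermodynamic stacking parameters are a standard, widely
reproduced choice of RNA dinucleotide physicochemical index; the table is
deliberately user-replaceable (`--dac-index-table`, TSV with an AA..UU
header), since no single index set is canonical for this feature family.
With N=3 indices the DAC block is 6 columns and the fused width at L=41 is
166.

**Fusion.** Column-wise concatenation in the fixed order
MisM | ASDC | DAC | ANF | PSTNP, labels prefixed by block name. The order is
part of the contract (supplying blocks in any other order is an error) so
that saved selections index a stable column space.

## Feature selection

A gradient-boosted tree ensemble is trained on the fused training matrix, and
each column's importance is the mean absolute Shapley attribution over the
training samples — the ordering a beeswarm plot displays. Attributions are
exact TreeSHAP values on the positive-class margin (log-odds), computed by
XGBoost's native `pred_contribs`. The correct Shapley kernel
|S|!(|N|−|S|−1)!/|N|! is used throughout; the test suite verifies the
efficiency axiom (Σφ_i + bias = margin) and agreement with a brute-force
enumeration of all 2^D coalitions on small models. For that enumeration, the
coalition value function mirrors TreeSHAP's: descending each tree, splits on
in-coalition features follow the sample, splits on absent features average
the children weighted by training cover. One numerical subtlety: threshold
comparisons are done in float32, as the booster does — with histogram-based
tree growth a split threshold can tie a data value exactly, and a float64
comparison can take the wrong branch.

Ties in the ranking break toward the lower original column index (stable
sort), making selection deterministic. Default K=64; top-K sets are nested in
K by construction.

## Modeling protocol

Per-class stratified 80/20 split: the training side takes ⌈0.8·n⌉ per class
(662 → 530 train / 132 test, reproducing the 132+132 independent set of the
benchmark protocol), with a seeded permutation.

Cross-validation (5- or 10-fold, stratified, shuffled with the configured
seed) refits *everything* per fold: PSTNPss on the fold's training sequences,
the ranking model, the top-K selection, and the final classifier. A
`selection_scope="global"` switch fits the propensity table and selection
once on the full data, to mimic protocols that select features before
cross-validating; it is off by default because it leaks test information.

Classifier defaults: 200 trees, learning rate 0.01, max depth 20,
min child weight 10, gamma 0.5, binary-logistic objective, seed 42,
`tree_method="hist"`, one thread (determinism), base score 0.5. The
remaining three parameters default to colsample_bylevel=0.8, reg_alpha=0.1,
reg_lambda=1.0; enabling `grid_search` resolves them over
{0.5, 0.8, 1.0} × {0.1, 1} × {0.1, 1} by internal 3-fold stratified CV on the
training partition (deterministic fast path off, faithful grid on).

Note that these defaults assume benchmark-scale data (hundreds of sequences
per class): min child weight 10 with a logistic hessian of at most 0.25 per
sample means trees cannot split below ~80 training sequences, and the model
degenerates to a constant 0.5 predictor. The test suite therefore uses a
lighter configuration for small fixtures and the published configuration at
the generator's study scale.

Baselines (RF: 200 trees, entropy, depth 20, min split 9, min leaf 5;
SVM: RBF, C=15, γ=0.001; KNN: 11 neighbors; Gaussian NB; logistic
regression) run on identical fold assignments and, by default, on the same
selected features as the boosted model; a `feature_space="hybrid"` switch
compares on the unselected fusion instead. RF's legacy "auto" max-features
setting maps to "sqrt" (its classifier meaning).

Persistence: one JSON archive holding the booster (XGBoost's own JSON
serialization), the propensity matrix, the index table, the selection and all
configs. Round-tripping reproduces predictions bit-identically.

## Evaluation conventions

Metrics come straight from the 2×2 confusion matrix (positive = 5hmC):
accuracy, sensitivity, precision, specificity, F1, MCC. Zero-denominator
cases return 0 and are flagged in `MetricsReport.degenerate` rather than
raising — the usual convention for undefined MCC/precision. AUC uses the
rank/Mann–Whitney formulation (ties count ½), which is exact and agrees with
trapezoidal ROC integration on tie-free data. Classification threshold is
fixed at 0.5. Log-loss clips probabilities at 1e−15. "Mean average loss" in
the error bundle is an alias of MAE: the name circulates in this literature
without an agreed formula, and MAE is the reading consistent with its
reported magnitudes.

## Synthetic data

The generator emulates the *structure* of the benchmark family — balanced
two-class sets of fixed-length windows (defaults: 662 per class, L=41, a
typical modification-window size) — with two orthogonal, encoder-visible
dials: a motif overwritten at a fixed position in each positive with
probability `motif_prob` (position-specific signal, default GACU at 19), and
per-class nucleotide composition vectors (global signal). Positives and
negatives are drawn from separate substreams spawned from one seed, so
resizing one class never perturbs the other.

What it does *not* emulate: real 5hmC sequence biology (TET context
preferences, transcriptome composition, homology structure between windows).
Passing pipeline tests on this generator demonstrates that the machinery
recovers planted statistical signal and sits at chance on exchangeable
classes — not that any particular accuracy will transfer to real data.

## Numerical and design choices

- Trinucleotide/dinucleotide orderings are lexicographic with A<C<G<U and
  fixed, so column labels are stable across runs.
- All encoders are deterministic; the CV report is a pure function of
  (data, configs, seed). Every CLI command draws randomness from a single
  `--seed` (default 42).
- Position-10 of the documented ANF example sequence evaluates to +0.3; the
  formula cannot produce negative densities.
- The mismatch membership matrix is symmetric, so window→k-mer crediting is
  implemented as a single matrix product against the exact k-mer spectrum.
- Exit codes in the CLI: 0 success, 2 validation error, 3 runtime error.

## Problem sizes used in the checks

The pipeline-recovery checks run at 200+200 sequences, L=41, 10-fold CV for
the planted-motif condition and 5 seeds × 5-fold for the exchangeable null;
encoder property suites use 100 random sequences. These sizes give stable
statistics for the stochastic assertions while keeping the whole suite quick
to run locally.

## Known limitations

- The DAC index table is a three-index thermodynamic default, not a
  curated conformational set; users comparing against other ASDC/DAC
  implementations should supply their own table.
- Feature selection uses path-dependent TreeSHAP; interventional
  (background-marginalized) attributions are available only through the
  brute-force oracle, which is exponential in feature count.
- `selection_scope="global"` exists for protocol comparison and is
  intentionally leaky; its CV numbers are optimistic.
- The published hyperparameters are consumed as given; no tuning beyond the
  printed grid is attempted.
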
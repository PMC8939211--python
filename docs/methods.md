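# Methods

This note records the models the package implements, the defaults it
ships, and the design choices made where the design was genuinely open.

## Metrics

Per-class scores are computed one-vs-rest from TP/FP/FN/TN counts:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
GM = √(precision·sensitivity), F1 (harmonic mean), and AGM
(GM + specificity·N_n)/(1+N_n) with N_n the negative-class proportion
and an explicit zero branch when sensitivity is 0.  AGM targets the
imbalance problem directly: it rewards sensitivity while charging for
lost specificity, more heavily the rarer the class.

**Definedness.**  Any ratio with a zero denominator is UNDEFINED and is
rendered as a dash.  The AGM boundary cases are resolved as: class
absent from the ground truth (TP+FN = 0) → UNDEFINED; class present but
never recovered (TP = 0 < TP+FN) → 0 via the zero-sensitivity branch;
no negatives at all (N_n = 0) → AGM reduces to GM.  Macro-averages are
means over the classes whose value is defined, and reports carry the
count of included classes; skipping (rather than zero-filling)
undefined classes matches how dashes behave in published comparison
tables.

**Aggregation levels.**  Residue-level reports pool one confusion per
class over all residues of all chains (pooling is additive, which the
tests verify).  Sequence-level values compute the metric independently
per chain and are the sampling units for the permutation tests; the
two aggregates differ in general and are never mixed.

## Inference

The paired Fisher–Pitman test conditions on the observed per-chain
differences d_i = a_i − b_i and flips their signs: for n ≤ 16 all 2ⁿ
arrangements are enumerated (exact); above that, r Monte-Carlo draws
from a seeded generator with p = (count+1)/(r+1), so p ≥ 1/(r+1) and
identical seeds reproduce identical p-values.  Arrangements tying the
observed statistic within 1e-12 count toward p (conservative).  Default
r = 9999.  These conventions (observed arrangement included, tie
handling, r) follow common permutation-test practice; they are this
package's choices, documented rather than inherited.

Cohen's paired d = mean(d)/sd(d) with the sample (n−1) standard
deviation; |d| is binned at 0.01/0.2/0.5/0.8/1.2 into
negligible/very small/small/medium/large, with "very large" above 1.2
(the open top bin needed a label; 1.2 is the conventional upper
breakpoint).  Sign convention: d > 0 means the first-named (baseline)
predictor is better on higher-is-better metrics.  sd = 0 with non-zero
mean yields UNDEFINED with a warning rather than ±∞.

Comparisons with fewer than 20 valid pairs — after dropping chains
where either side is UNDEFINED — are not tested and render as a dash.
Both one-sided directions are always run so a significantly *worse*
baseline is flagged too.  No multiple-testing correction is applied;
reports carry the number of tests run so readers can apply their own.

## Analysis conventions

Per-class "accuracy" rows in comparison tables are per-class recall
over pooled residues (per-class accuracy including true negatives would
be dominated by the majority class and is not informative here).  Q8 at
the sequence level is per-chain accuracy, defined for every non-empty
chain.  Neff bins take floor(Neff) and drop bins under 20 chains.
Chains where every predictor scores sequence-level macro-AGM below 0.3
are flagged as likely data defects (in real data, chains with many
unresolved residues behave this way; the synthetic gap fixture emulates
them).

## The network

Inputs are per-residue blocks: one-hot amino acids (20 columns,
all-zero rows for non-standard residues — this keeps exactly 20 columns
rather than inventing an unknown class), PSSM (20), HHM profile (30),
and a windowed contact map (W = 50).  Each input has its own
contractive path; down-blocks are two convolutions (kernel 7) with
dropout 0.1 between them, followed by max-pooling by 2.  After each
down-block the features of all inputs are concatenated and passed to
the matching up-block as a skip connection, gated by an additive
attention gate (1×1 convs: sigmoid(ψ(relu(θx + φg))) scaling the skip
features x with the up-path features g as gating signal; the gate's
internal width is half the skip width).  A single expanding path with
nearest-neighbour upsampling reconstructs per-residue features, and two
1×1 softmax heads emit SS3 and SS8 probabilities.  The loss is the
unweighted sum of the two masked categorical cross-entropies; padded
positions (chains are right-padded with zero features to max_len = 704)
never contribute.  Depth 4 and kernel 7 are inherited defaults from the
single-input predecessor architecture and configurable; max_len must be
divisible by 2^depth.

PSSM and HHM columns are standardised to zero mean and unit SD using
statistics of the training split only; the statistics travel with the
checkpoint.  Contact windows are already in [0, 1] and pass through
unstandardised.  The contact window of residue i covers offsets
−W/2 … −1, +1 … +W/2 (self excluded, zero-padded at chain ends); the
exact upstream windowing dialect is not standardised, so this one is
documented as the package's own.

HHM profiles store scores as −1000·log2(p) with `*` for probability
zero; both are converted to probabilities 2^(−score/1000) at read time
(`*` → 0), so standardisation always sees probabilities.

The network runs on a small reverse-mode autodiff engine over numpy
arrays written for this package (taped graph; conv1d via im2col;
Adam).  Gradients are verified against central finite differences in
the test suite.

**Training schedule** (defaults): Adam, batch 8, initial lr 1e-3,
lr × 0.1 after 4 epochs without validation-loss improvement, stop after
7 such epochs, return the weights of the best validation epoch.
Ensembles average member softmax outputs element-wise; members must
share one architecture config.

**Stratified folds.**  Each chain gets a 9-bit stratum: length above
the mean length, plus, per class, occurrence count above the mean
occurrences per chain (means over all chains, zero-occurrence chains
included).  Chains are dealt within each stratum in blocks of k, so
per-stratum fold counts stay within ±1 and fold sizes are exact.  Plain
round-robin, however, cannot balance the rarest classes: pi-helix
residues live in a few hundred chains scattered over ~100 distinct
strata, and measured per-fold I frequencies deviated by up to ~36%
relative.  A deterministic repair pass therefore swaps chains between
the extreme folds for each of the three rarest classes, picking swap
partners with the most similar residue profiles so common classes stay
balanced; fold sizes are preserved exactly.  On a 1000-chain synthetic
fixture all eight per-fold class frequencies land within ~10% relative
of the global values.

## The synthetic generator

Ground-truth labels are a first-order Markov chain over the eight
states.  Self-transitions encode expected run lengths (geometric with
mean 1/(1−p_self)); off-diagonal rows are a proportional allocation
T[s,t] = (1−p_s)·a_t/Σ_{u≠s}a_u whose weight vector a is solved by
fixed-point iteration so the requested class frequencies are exactly
stationary.  Infeasible frequency/run-length combinations raise rather
than being silently adjusted.  The default preset —
G .035, H .350, I .003, B .015, E .220, S .085, T .110, C .182, with
run lengths H 9, E 5, C 3, T 2.5, G 2.5, S 2, I 1.8, B 1.2 — is a
qualitative match to the imbalance of real benchmark sets (H ≫ E >
C,T > S,G > B ≫ I, with the H:G ratio fixed at the canonical 10:1 of
the accuracy paradox); exact benchmark frequencies are not claimed.
Amino-acid sequences are uniform random (sequence content carries no
signal here by design), and Neff is lognormal (μ_log 1.3, σ_log 0.7,
capped at 40), spanning the 1–15 range where profile quality matters.

Simulated predictors pick, per residue, the true class with probability
recall(class) and otherwise a confusable class (uniform or user-
weighted); the emitted row is a softmax peaked on the chosen class with
temperature 0.25 (peak ≈ 0.89).  Recall can increase linearly with the
chain's Neff to emulate profile-quality dependence.  Pseudo-features
are class mean vectors plus Gaussian noise (logistic-squashed for the
HHM block to stay in [0, 1]; a banded, class-modulated matrix clipped
to [0, 1] for contacts).

**What this does not emulate**: real sequence–structure coupling,
non-geometric segment-length distributions, beta-sheet pairing
constraints, profile columns with realistic amino-acid semantics, or
correlated errors between predictors.  Passing tests demonstrate the
correctness and calibration of the *evaluation machinery* and the
trainability of the architecture, not real-data accuracy.

## Problem sizes used in the checked results

The statistical checks run at sizes chosen to finish comfortably on a
single CPU while keeping their power: null calibration uses 500
replicate datasets of 200 chains (rejection count compared to the
binomial 99% band at α = 0.01); injected-effect power uses 100
replicates; Monte-Carlo/exact agreement uses 100 random difference
vectors with r = 50 000; the overfit check trains a depth-2, 16-filter
net on 5 chains of ≤ 64 residues; fold balance uses 1000 chains.

## Known limitations

* The autodiff engine is single-threaded float64 numpy; training is
  intended for small and mid-size experiments, not for datasets of
  10 000 chains at full length.
* Exact permutation enumeration is capped at n = 16 pairs (2¹⁶
  arrangements); beyond that p-values are Monte-Carlo with resolution
  1/(r+1).
* The PSSM/HHM readers cover the common ASCII layouts (and the
  package's own writers round-trip exactly); exotic dialect variants of
  upstream tools may need pre-conversion.
* SOV-style segment-overlap scores are out of scope; so is computing
  PSSM/HHM/contact features themselves.
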
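# Methods

## Problem and model

The package classifies averaged event-related potentials (ERPs) recorded at
the parietal midline into P3 (a P300 deflection is present; the subject
recognizes the probe stimulus) and non-P3 responses, the decision at the core
of P300-based concealed-information testing. The classifier is an extreme
learning machine (ELM): a single-hidden-layer feedforward network whose
hidden layer — input weights wᵢ and biases bᵢ, i = 1…K — is drawn uniformly
on [−1, 1] and never trained. With sigmoid activation σ, the hidden-layer
output matrix over N samples is H[j, i] = σ(wᵢ·xⱼ + bᵢ), and the output
weights are the minimal-norm least-squares solution β = H⁺T (Moore–Penrose
pseudoinverse). Targets are encoded on a single output node as T ∈ {−1, +1};
predictions take the sign of Hβ, with a score of exactly 0 classed +1. When
K = N and H is invertible the network interpolates its training data; among
all least-squares solutions, the pseudoinverse gives the smallest ‖β‖, the
property associated with ELM generalization.

Model selection is the package's centerpiece: the feature-subset size S and
the hidden-node count K are optimized **jointly** rather than fixing either.
Features are ranked once per cross-validation fold by descending F-score

F_i = [(x̄ᵢ⁺ − x̄ᵢ)² + (x̄ᵢ⁻ − x̄ᵢ)²] / [s²ᵢ⁺ + s²ᵢ⁻],

with class sample variances using 1/(n−1). For S = 1…D (D = 31 features) the
top-S features feed ELMs with K = S…S+k_span, and each (S, K) cell is scored
by balanced training accuracy under the nested cross-validation below. This
couples the size of the network to the size of the feature space instead of
tuning K by hand.

## Cross-validation and the selection rule

Subject-wise cross-validation (SWCV) defines the outer folds: subjects are
sorted by ID within each class and fold f holds out the f-th positive and
f-th negative subject, so no subject contributes to both training and
evaluation and the fold count equals the per-class subject count (14 at the
emulated study's scale). Inside each outer fold a stratified k-fold CV
(default 10) runs over the training subjects' responses. Per cell, the
fold-level sensitivity/specificity is the mean over inner validation folds;
TR_sen and TR_spe average these over outer folds, and
BA_train = (TR_sen + TR_spe)/2.

Selection prefers parsimony: among all cells whose BA_train is within
`parsimony` percentage points (default 0.5) of the grid maximum, the cell
with the smallest S, then smallest K, is chosen; `parsimony = 0` reproduces
the strict arg-max. The default acknowledges that near-ties in training
accuracy are common on the grid and a materially smaller network is the
better model; it is configurable precisely because it is a judgment call.

Ranking **and** [−1, 1] normalization are fit inside each outer fold on the
training subjects only. An alternative reading — ranking once on all data
before the CV — is available as `global_ranking=True` for comparison, but it
leaks held-out subjects into selection and is off by default. Test metrics
(TE_sen, TE_spe, BA_test = their mean) come from per-fold final models
retrained on the fold's full training subjects at (S\*, K\*).

The PCA route replaces ranked features with principal components of the
normalized training rows (eigen-decomposition of the ddof=1 sample
covariance, descending eigenvalues, projection of centered rows), with the
retained dimension d in the role of S. Eigenvector signs are fixed by making
each vector's largest-magnitude entry positive so reruns are identical.

## Features

- Time-domain (post-stimulus window, t ≥ 0): V_max, its latency t_max
  (measured from stimulus onset), R_LA = t_max/V_max (0 by convention when
  V_max = 0), V_min, V_ptp = V_max − V_min, positive area
  A_p = Σ max(x, 0)/fs (rectangle rule, µV·s).
- Frequency-domain, computed on the full epoch: Burg AR spectrum
  (order 20, 512 frequencies on [0, fs/2]; the order is a standard choice for
  1 s ERP epochs — the method is parametric and the spectrum is smooth in the
  band of interest). f_max is the argmax frequency, f_mean the
  power-weighted mean, A_lf the rectangle-rule power in 0.1–3.9 Hz — the
  band containing the P3. A zero signal maps to an all-zero spectrum and
  (0, 0, 0) by convention.
- Time–frequency: a 6-level discrete wavelet decomposition produces seven
  coefficient sets (D1…D6, A6); the features are the 22 level-6
  approximation coefficients, whose band [0, fs/2⁶] = [0, 3.90625 Hz]
  matches the P3's spectral content. The filter is db8 (length 16) with
  zero-padding (full convolution): under the cascade n_j = ⌊(n_{j−1}+L−1)/2⌋
  a 500-sample epoch yields 500→257→136→75→45→30→22 — the unique standard
  filter-length/boundary combination giving exactly 22 coefficients, which
  is why it is the default; family, level and mode are exposed, and any
  combination not yielding 22 raises with the computed count.
- Normalization: x' = 2(x − min)/(max − min) − 1 with limits from training
  rows; constant features map to 0; unseen values are not clipped.

## The simulator

`SimConfig`/`generate_dataset` emulate averaged Pz probe responses: epochs
from −0.2 to +0.8 s at 500 Hz (500 samples; sample i at t0 + i/fs), a
raised-cosine (Hann) P3 bump of width 0.3 s peaking 10 µV at 0.35 ± 0.03 s
in the positive class, per-subject amplitude offsets (SD 2 µV), trial-level
amplitude variation (SD 1 µV) and additive noise (white, SD 5 µV, or AR(1)
with matched marginal variance to mimic the colored EEG background).
Preprocessing subtracts the pre-stimulus mean from each trial and averages
consecutive, non-overlapping groups of 5 trials in input order, dropping the
remainder; 14 subjects per class × ⌊105/5⌋ averages gives 294 averaged
responses per class, matching the emulated protocol's ballpark of ~300 per
group. The defaults produce a clean, near-separable problem — real EEG has
ocular artifacts, non-stationary background, latency drift, overlapping
target/irrelevant responses and habituation that the simulator does not
model, so passing tests demonstrate correctness of the machinery and
recovery of planted structure, not field performance on recorded EEG.

## Numerical choices

- Pseudoinverse: SVD-based with singular values below 1e-10·σ_max treated as
  zero (`rcond`, exposed).
- Grid-search inner loop: output weights are solved by normal equations with
  a Cholesky factorization on nested column blocks — per (fold, S) one
  random hidden layer of S+k_span nodes is drawn and cell K uses its first K
  columns. Sigmoid hidden matrices on continuous data are almost surely full
  column rank for K ≤ N, where the Cholesky solution equals the minimal-norm
  LS solution; K > N or a failed factorization falls back to the SVD route.
  This cuts the 651-cell × 14-fold × 10-split sweep by an order of magnitude
  while the user-facing `ELMClassifier`/`elm_train` and the per-fold final
  refits keep the pseudoinverse exactly.
- Seeding: a single master seed fans out through `SeedSequence` spawn keys to
  the simulator, each fold's inner-CV shuffle, each (fold, S) hidden-layer
  draw and each fold's final refit, so whole runs are bit-reproducible and
  no two draws share a stream.
- Ties: F-score ranking sorts stably, breaking ties by original column
  index; a zero within-class-variance feature with separated means scores
  +inf and ranks first; 0/0 scores 0. ELM scores of exactly 0 predict +1.
  The paired t-test on per-fold accuracies returns p = NaN with a warning
  when the differences have zero variance.
- Degenerate inputs: baseline correction requires a pre-stimulus interval;
  F-scores require ≥ 2 members per class; SWCV requires ≥ 2 subjects per
  class, equal class counts and no duplicated or class-ambiguous subjects;
  Burg requires order < signal length.

## Problem sizes in the test suite

The structure-recovery checks run at 10+10 subjects with 200 responses per
class over a full 31 × 21 grid (about 5 s per search), with 5 seeds for the
planted-signal case and 10 for the pure-noise chance-level case; the
simulator statistics use 2000 trials per class. These sizes give stable
statistics while keeping the default suite quick to run.

## Known limitations

- Binary, single-electrode (Pz) classification only; no multi-class or
  multi-channel support.
- The BPNN/SVM comparison models are not implemented; the evaluation
  utilities (`paired_ttest`, `evaluate --compare`) accept their per-fold
  accuracies from external sources.
- Wall-clock training/testing times are reported as diagnostics in the text
  report only; they are machine-dependent and deliberately excluded from the
  deterministic result JSON.
- The grid search requires equal subject counts in the two classes (the
  fold construction pairs one held-out subject per class); unbalanced
  designs are rejected rather than paired heuristically.
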
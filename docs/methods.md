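# Methods

This note documents the models and procedures implemented in `somnoband`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot show.

## Signal model and epoching

The classification unit is a fixed-length, non-overlapping epoch of the
two central EEG derivations C3-A2 and C4-A1 at 100 Hz. Epoch duration
defaults to 30 s (3000 samples), the standard polysomnography scoring
window, and is configurable everywhere. When epochs are cut from a
continuous annotated recording, an epoch takes the label of the event
covering at least 50% of it (largest overlap wins) and is otherwise
labeled normal breathing; the trailing partial epoch is dropped. Signal
units are treated as microvolts but never used quantitatively — sample
entropy is scale-invariant by construction (its radius tracks the signal
standard deviation) and variance is reported in input units².

## Sub-band filter bank

Five band-pass filters cover the canonical EEG bands: delta 0.5–4 Hz,
theta 4–8, alpha 8–12, sigma 12–16, beta 16–40. Each is an order-4
Butterworth design in cascaded second-order sections (numerically stable
at the narrow delta band), applied forward–backward (`sosfiltfilt`).
Zero-phase application was chosen so that the features are invariant to
filter group delay; it doubles the effective order and squares the
magnitude response, giving ≈ −2 dB at band edges and steep roll-off
(< −30 dB one octave out at these widths). The band table and order are
configurable; no notch filtering or artifact rejection is performed.

## Features

Per band-limited signal x of length N:

* **Variance** — population form, (1/N) Σ (xᵢ − x̄)², not the N−1
  sample estimator.
* **Sample entropy** — SampEn(m, r) = −ln(B^{m+1}/B^m) with the
  Richman–Moorman convention: templates of length m and m+1 both drawn
  from starting points 1..N−m, Chebyshev distance, self-matches excluded.
  Defaults m = 2, r = 0.2·std(x), with the standard deviation taken from
  each band-limited signal itself so the statistic stays scale-invariant
  band-wise. A constant signal yields exactly 0. If no template pair
  matches at length m+1 (−ln 0), the finite upper bound
  −ln(2/((N−m−1)(N−m))) is returned with a warning rather than +inf,
  so one maximally irregular signal cannot poison a feature matrix.
  The production kernel is a numba-compiled O(N²) pair count; the test
  suite verifies it against an independent per-template transcription of
  the definition to 1e-12 over hundreds of randomized series.

The feature matrix has 20 columns — variance then sample entropy, each
channel-major (C3, C4) and band-minor (δ, θ, α, σ, β) — with a typed
column registry carried through selection and reporting.

## NCA feature selection

Weights are learned with the diagonal NCFS formulation: distance
D_w(xᵢ,xⱼ) = Σ_l w_l²·|x_il − x_jl|, reference probabilities
p_ij = softmax_j(−D_w) with self excluded, and objective
Σᵢ Σ_{j≠i, y_j=y_i} p_ij − λ Σ w_l². Optimization is L-BFGS from w = 1
with an analytic gradient; |w| is reported since only w² enters the
metric. Features are z-scored using training-data statistics only.

λ is tuned over 16 equally spaced values spanning [0, 15/n_train] by
stratified 5-fold cross-validation, scoring the 0/1 loss of a 1-NN rule
in the learned weighted metric (the natural NCA decision rule); ties
break toward the larger (sparser) λ. Selection keeps features with
w ≥ T = τ·max(w), τ = 0.02.

A property worth knowing: the soft leave-one-out objective can retain
small nonzero weights on pure-noise features when a problem has few
informative dimensions and moderate n — those weights genuinely increase
the training objective (finite-sample overfitting intrinsic to NCFS),
and ridge values in the tuned range do not remove them. With several
informative columns and three classes (the regime of the 20-column
matrix) recovery is clean: informative columns are selected with high
precision across seeds.

## Classifiers and cross-validation

All three classifiers support inverse-frequency class weighting
w_c = n_total/(n_classes·n_c), which favors minority classes (central
apnea is typically the rarest event type):

* **KNN** — Euclidean, k = 5 by default (odd, avoids three-way ties; the
  neighbor count is otherwise unconstrained by the method). Weighting
  enters the vote: each neighbor contributes its class weight; ties break
  toward the class with the smallest aggregate neighbor distance.
* **SVM** — RBF kernel, C = 1, kernel scale 1/(d·var(X)), one-vs-one
  decomposition of the 3-class problem with majority vote; class weights
  scale the per-class penalty.
* **Random forest** — 85 trees, bootstrap + per-node feature
  subsampling, class-weighted impurity, seeded.

Evaluation uses stratified 10-fold cross-validation (stratification keeps
all three classes in every fold, so per-class accuracy is always
defined), pooled across epochs. The averaged confusion matrix is the
element-wise mean of the row-normalized per-fold matrices (per-class
rates); raw counts are also summed, and the pooled count matrix feeds the
metric battery: per-class and macro recall, precision, F1, overall
accuracy and Cohen's kappa. Degenerate 0/0 ratios (a fold missing a
predicted class) report 0 with a warning. Precision is TP/(TP+FP); F1 is
the harmonic mean of its own precision and recall.

## Selection placement: two protocols

`per_fold` (default) refits feature selection inside every outer training
fold, so reported accuracy is leakage-free. Re-running the full λ grid
search inside every fold would multiply cost ~80-fold for little benefit
at these sample sizes, so per-fold selection fits weights at the fixed
default λ = 1/n_train. `paper` mirrors a common published design:
selection once on a stratified 75/25 split with the full grid search,
then 10-fold CV of the selected set over all epochs — optimistically
biased, provided for comparability. Epoch-pooled CV is used in both; a
recording that contributes many epochs will inflate accuracy relative to
subject-grouped CV, which is out of scope here.

## Synthetic data

The generator emulates exactly the structure the classifier exploits.
Each epoch is a sum over bands of unit-variance band-limited noise (white
noise passed through the analysis filter bank — not pure tones, so
spectra are EEG-like and sample entropy varies smoothly), scaled by a
per-class band-power profile, plus class-dependent broadband white noise
that drives sample entropy. Both channels share the oscillatory
components with class-specific C3/C4 gains and carry independent noise.

Default profiles (relative power over δ, θ, α, σ, β; noise mix; C3/C4
gains):

| class | band powers             | noise | gains       |
|-------|-------------------------|-------|-------------|
| NB    | 0.8, 0.8, 1.0, 0.6, 0.8 | 1.5   | 1.00 / 1.00 |
| OSA   | 3.5, 0.8, 0.5, 0.3, 0.3 | 0.35  | 1.00 / 1.35 |
| CSA   | 1.8, 2.2, 0.5, 0.3, 0.3 | 0.5   | 1.25 / 0.85 |

Directionally these follow the apnea literature — apnea-like epochs have
elevated low-frequency power and reduced complexity, OSA and CSA are
separated by their delta-vs-theta balance and hemispheric asymmetry — but
the contrasts are deliberately clear-cut so pipeline properties hold with
margin. Consequences: cross-validated accuracy on the default profiles
saturates near 100%, which validates the machinery (filtering, entropy,
selection, weighting, CV bookkeeping), not clinical performance. The
generator omits artifacts, non-stationarity, inter-patient variability,
arousals and stage effects; passing tests therefore say nothing about
accuracy on real polysomnography. A separate tabular generator emits
Gaussian feature matrices with a known informative-column set (cycled
mean-shift patterns of a configurable effect size) for testing selection
and classification in isolation, including the reported clinical class
imbalance 1229/812/1418.

## Numerical and degenerate-input choices

* SampEn: counts are exact integers; the m and m+1 counts come from one
  pass; series shorter than m+2 are rejected.
* Filter design rejects band edges at or above Nyquist; epochs must be
  longer than 3× the filter order.
* NCA: softmax rows are max-shifted before exponentiation; an all-zero
  weight vector is a selection error (λ too large); single-class input is
  rejected.
* Kappa is undefined when chance agreement p_e = 1 (all mass in one
  marginal cell) and raises with a message.
* Determinism: every stochastic step (generator, fold shuffles, RF, SVM)
  derives from an explicit seed; pipeline artifacts contain no
  timestamps, so reruns are byte-identical.

## Problem sizes

The bundled evaluation script simulates 600 epochs (200 per class) of
30 s at 100 Hz and runs the `paper` protocol with all three classifiers;
the test suite uses 150–600-row tabular problems and 300-epoch
simulations. These sizes give stable estimates of every property the
package asserts while keeping a full run in the minutes range on a single
CPU core.

## Known limitations

* No artifact rejection, re-referencing, sleep staging or mixed-apnea
  handling; the event alphabet is fixed at {OSA, CSA, NB}.
* Epoch-pooled CV (see above); `--group-by-subject` evaluation is not
  implemented because the synthetic generator has no subject structure.
* EDF support covers signal + annotation reading via `mne`; EDF writing
  is not provided (the portable epoch format is CSV + JSON).
* NCFS weight overfitting in low-dimensional two-class regimes, as noted.
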
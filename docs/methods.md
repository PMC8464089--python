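# Methods

## Pipeline model

Each single-channel EEG segment is treated as a stationary waveform whose
irregularity carries class information. The pipeline is: band-pass
decomposition into delta/theta/alpha/beta rhythms → six nonlinear measures
per signal (original + four rhythms = 30 features) → ReliefF ranking →
sequential feature addition into classifiers under nested stratified
ten-fold cross-validation. Accuracy is the mean of outer-fold accuracies
in percent; a pooled-prediction aggregation is available as an option.

## Rhythm decomposition

Fourth-order Butterworth band-pass filters (delta 0.5–4, theta 4–8, alpha
8–14, beta 14–30 Hz) designed in second-order sections for numerical
stability at the narrow low-frequency bands. The filter is applied
forward–backward (zero phase) by default: the fractal measures are
waveform-shape sensitive, and a causal pass would impose a band-dependent
phase distortion. Forward–backward application doubles the effective
attenuation; the "fourth-order" contract refers to the designed prototype,
and `magnitude_response(..., zero_phase=True)` returns the squared
single-pass gain accordingly. A causal single-pass switch exists for users
who need causality. No edge trimming is performed in the pipeline —
features are computed on the full filtered length; tests that verify gains
discard edges (and measure steady-state amplitude by quadrature
projection) because filter transients are a property of the measurement,
not of the filter.

## Nonlinear measures — numerical choices

- **Higuchi**: ordinary least squares over all p = 1..k_max on
  log A(p) vs log(1/p), natural logs, no point weighting. Two saturation
  scales k_max ∈ {30, 45} are exposed; both are computed from a single
  length-curve evaluation (the smaller scale fits a prefix of the points).
  A constant signal has zero curve length and raises a defined error.
  Precondition: signal length > 4·k_max.
- **Katz**: abscissa is the sample index (unit spacing), not seconds —
  Katz's construction on sampled waveforms; time-scaling the abscissa
  would silently change K. Base-10 logarithms. n = U/m = Y−1 exactly.
- **Hurst (R/S)**: block lengths follow the halving schedule M, M/2, …
  stopping at min_block = 16 (shorter blocks make R/S unstable);
  non-overlapping blocks, trailing remainder dropped; denominator is the
  population standard deviation √((1/m)Σ(Tⱼ−a)²). Blocks with zero SD are
  excluded; fewer than three usable block lengths is an estimation error.
  The raw estimator is reported unclipped (finite-sample bias can push it
  slightly outside [0, 1]); the feature vector clips to [0, 1].
- **Lempel–Ziv**: binarization margin is the mean or the median; samples
  exactly equal to the margin map to 0 ("1 iff strictly above"),
  deterministically. The parser is the LZ76 exhaustive-history scheme
  (each component is the shortest prefix of the remainder absent from the
  extended history); a final incomplete component counts as one.
  Normalization C = c/(m/log₂ m).

Feature naming is `MEASURE(SOURCE)` — e.g. `KFD(Beta)`,
`HFD_kmax=45(Original Signal)` — stable across runs. Per-measure failures
(e.g. Hurst on a constant segment) become NaN entries flagged on the
vector and are dropped from the feature table with a logged warning.

## ReliefF

Multi-class ReliefF with k = 10 neighbours and all instances (no
subsampling), Manhattan distance on range-normalized features, the same
normalized absolute difference as the per-feature diff, and miss
contributions weighted by P(c)/(1−P(class(R))). Zero-range features get
weight exactly 0. Ties in neighbour distance and in final weights are
broken by original row/column order, making the procedure fully
deterministic. All 30 features are continuous; no nominal-feature branch.

## Classification protocol

Outer stratified 10-fold; per outer fold an inner stratified 10-fold on
the training part selects the grid point with the best mean inner
accuracy, ties going to the first-listed (simplest) point. z-score
standardization is fit on the training part only. Grids: MLP hidden sizes
{2, 5, 10, 20, 40} (single hidden layer, tanh activation, cross-entropy
objective, Adam, iteration cap 400); linear-SVM C ∈ {0.01…100}; RBF-SVM
C ∈ {0.01…100} × γ ∈ {10⁻³…10} (log-spaced). Multi-class SVM uses
one-vs-one voting. The inner fold count drops to the smallest training
class size when that is below 10, so small matrices remain evaluable.

Ranking mode "global" ranks once on the full problem matrix — it mirrors
a single published ranking and slightly optimistically re-uses all labels;
"foldwise" recomputes the ReliefF ranking inside every outer training
fold and is the leakage-safe mode for honest validation. A test verifies
structurally that foldwise ranking only ever sees training rows.

Class imbalance (e.g. 400 vs 100 in ABCD/E) is left as-is: plain accuracy
is the reported metric.

## Synthetic data

`generate_fgn` synthesizes fractional Gaussian noise by circulant
embedding of the exact fGn autocovariance γ(k) = ½(|k+1|²ᴴ − 2|k|²ᴴ +
|k−1|²ᴴ) — an exact method, chosen over approximate spectral synthesis
because estimator validation needs an oracle whose Hurst index is not
itself an approximation. `generate_weierstrass` sums
λ^(−kH) cos(2π λᵏ t) with H = 2 − dim and λ = 3 on [0, 1); harmonics above
the representable frequency are dropped (their amplitudes are
geometrically small).

The Bonn-mimic corpus emulates the *structure* of the five-collection
benchmark: 5 classes × 100 segments × 4097 samples (= round(23.6 s ×
173.61 Hz)) at 173.61 Hz. Class recipes (band-limited Gaussian noise +
broadband white noise, amplitudes in µV): A/B are alpha-dominated with the
most broadband roughness; C/D mix delta/theta at intermediate roughness
and larger amplitude; E superimposes a large (≈400 µV) ~1 Hz oscillation,
0.5–2 Hz band noise and broad biphasic spike-wave transients (1.5/s,
100 ms) over very little broadband noise — high amplitude but a smooth
waveform, so its Katz dimension is the lowest of the five classes while
its amplitude is the highest, reproducing the discriminative direction of
ictal versus normal EEG. The recipes make no claim of clinical realism:
there is no 1/f background, no artifacts (EMG/EOG), no nonstationarity
within segments, and classes are far better separated than real
interictal/ictal EEG — so passing pipeline tests demonstrates the
machinery (filters, features, ranking, CV) end to end, not clinical
performance. Accuracies on this corpus are not comparable to accuracies
on the real benchmark.

All generators are pure functions of (parameters, seed); the corpus
writer emits the Bonn on-disk convention (class folders, one rounded
integer sample per line) so synthetic and real corpora are
interchangeable to the reader.

## Problem sizes used in the shipped analyses

Estimator validation uses n = 4096 samples and 20 seeds per condition.
The corpus analyses use the full 500-segment synthetic corpus; the
sequential-curve driver defaults to the first 10 ranked features and the
SVM classifiers, which already reach their optima on this corpus — the
full 30-feature curve and the MLP are available by flag. The
label-permutation null uses 10 permutation seeds.

## Known limitations

- Published accuracies on the real Bonn recordings depend on classifier
  internals (Levenberg–Marquardt MLP training, LIBSVM numerics) that this
  package deliberately does not replicate; with the real corpus supplied
  the pipeline runs unchanged but numbers will differ at the margin.
- The R/S Hurst estimator carries the classical small-sample bias toward
  0.5 (recovery MAE ≈ 0.04 at n = 4096 over H ∈ {0.3…0.9}); no
  Anis–Lloyd correction is applied, matching the plain rescaled-range
  definition.
- Katz dimension depends on the amplitude scale (unit abscissa); feature
  values are therefore only comparable across segments measured in the
  same units, as in the Bonn convention (µV).
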
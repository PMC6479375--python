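# Methods

This note records the statistical model behind `delda`, the parameter
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data experiments do and do not demonstrate.

## Signal model and differential entropy

Band-pass filtered EEG is treated as a zero-mean stationary Gaussian
process per channel and band. Under that assumption the differential
entropy of band *i* is `h_i = ½ ln(2πe σ_i²)` nats — a monotone transform
of band power — and estimating it reduces to estimating the band variance.

Estimation policy (`DEConfig`):

* **Window length 1 s, non-overlapping** (`window_seconds=1.0`,
  `window_overlap=0`). One-second DE windows are the established convention
  for this feature family; the trial-level feature is the **mean** over
  windows, which matches a one-feature-vector-per-clip sample structure.
* **Variance estimator**: maximum likelihood (mean-removed, divide by N).
  This is the plug-in estimator matching the Gaussian entropy formula; at
  N = 200 samples per window its bias (−1/N inside the log, ≈ 0.0025 nats)
  is negligible against window-to-window spread.
* **Natural logarithm** throughout, so the 2πe constant is exact and scale
  changes shift DE by exactly `ln c`.
* **Variance floor 1e-12** replaces −∞ on degenerate (flat) windows, with a
  logged warning. Any floored window indicates pathological input, not a
  tuning opportunity.

For a band of width B Hz observed for T seconds per window and averaged
over m windows, the DE estimator's standard error is approximately
`½·sqrt(2/(2·B·T·m))` (band-limiting reduces the effective degrees of
freedom to ≈ 2BT per window). Tests use this expression for their
tolerances rather than fixed magic numbers.

## Band decomposition

* **Bands**: Delta 1–3, Theta 4–7, Alpha 8–13, Beta 14–30, Gamma 31–50 Hz.
  The printed edges leave spectral gaps (3–4 Hz, …); the gaps are kept
  rather than inventing contiguous boundaries.
* **Filter**: 5th-order Butterworth band-pass in second-order sections,
  applied forward-then-backward (`sosfiltfilt`) for zero phase. Zero-phase
  filtering keeps the Gaussian marginal intact and introduces no group
  delay; the effective magnitude response is the squared single-pass
  response.
* **Edge handling**: odd-reflection padding of up to three periods of the
  band's low edge, capped at signal length − 1. Signals shorter than three
  times the filter's minimal padding are rejected.
* **Combined band** = column-wise concatenation of the five per-band
  feature tables (not a single 1–50 Hz filter): the per-band tables are
  first-class objects and concatenation is what yields the 310-dimensional
  combined feature vector.

## Fisher discriminant reduction

Scatter matrices are computed by direct summation of centered outer
products (`S_w`) and count-weighted mean deviations (`S_b`); the identity
`S_t = S_w + S_b` is enforced as a test invariant at 1e-8 relative.

* **Solver**: generalized symmetric eigenproblem `S_b w = λ S_w w`
  (`scipy.linalg.eigh`), top `d ≤ K−1` eigenvectors. This is the classical
  simultaneous-diagonalization solution: each direction maximizes its
  Rayleigh quotient `wᵀS_b w / wᵀS_w w` subject to generalized
  orthogonality to the preceding ones. A product-of-quotients form of the
  objective is sometimes written down for this method, but that product is
  not what the eigen-solution maximizes (a repeated copy of the best single
  direction always beats it whenever λ₁ > λ₂); the per-direction quotient
  property is the one implemented and tested, including against a 1°
  brute-force direction grid.
* **Shrinkage**: `S_w + γ·(tr(S_w)/n)·I` with default γ = 1e-6. With 310
  features and ~472 training rows `S_w` can be ill-conditioned; the scaled
  ridge keeps the solve stable while perturbing well-conditioned problems
  by a relative 1e-6. γ = 0 is allowed and raises a clear error if `S_w`
  is singular.
* **Determinism**: eigenvectors are unit-normalized, the sign is fixed so
  the largest-magnitude entry is positive, and ties in eigenvalue are
  ordered by that entry's row index — re-fitting identical data is
  bit-identical.
* **No leakage**: the projection (and the centering mean) is fitted on the
  training split of every resampling fold and applied frozen to the
  validation split. Whether the original experiments refit per fold is
  unknowable from their description; fitting on all data would leak label
  information into the features, so the conservative protocol is used.
* **Default d = K−1 = 2**, the maximal informative rank of `S_b`.

## Evaluation harness

* **Split protocol**: repeated stratified 70/30 hold-out (default 200
  repeats; the desk-scale runs here use 20), with stratified k-fold CV
  available as an alternative mode — the two protocols are both described
  in the literature this design follows, and they are not interchangeable,
  so both ship. Splits are reproducible from `(seed, repeat_index)` alone.
* **Classifiers** (fixed hyperparameters): k-NN k=20; logistic regression
  L2, C=1; SVM with **RBF** kernel, C=1 (an alternative linear-kernel
  description exists in the source material; the tuned-experiment value is
  used and the kernel is configurable); random forest 120 trees, depth 10,
  min split 8; MLP hidden (64, 32), ReLU, Adam, batch 32, learning rate
  1e-4, max 200 epochs, no early stopping. Stochastic classifiers are
  seeded per split.
* **Metrics**: accuracy, macro-averaged precision/recall/F1 (classes are
  balanced, so macro equals weighted), and Cohen's kappa
  `(p_o − p_e)/(1 − p_e)` with chance agreement from marginal products.
  Metric computation is delegated to scikit-learn behind the harness
  surface; hand-evaluated confusion-matrix cases pin the definitions in
  the tests.
* **Timing** records classifier fit+predict wall-clock per split only
  (feature extraction is timed separately at the pipeline level). Timing
  is written to its own TSV so metric tables are byte-stable across
  re-runs; absolute times are hardware-dependent and only *within-machine
  comparisons* (e.g. 2-feature vs 310-feature SVM) are meaningful.

## Synthetic data generator

Each trial is a sum over bands of band-limited Gaussian noise: white noise
is pushed through the same zero-phase band-pass filters the pipeline uses
and scaled so the band component's variance equals
`exp(base + effect[class, band]·loaded(channel) + jitter[subject, channel,
band])`, plus a broadband floor (variance 0.01). Scaling uses the filter's
analytic white-noise variance gain `mean(|H|⁴)` over a dense frequency
grid, so the ground-truth variances are exact, not empirical. The ground
truth also reports each band component's predicted variance after the
pipeline re-filters it (`mean(|H|⁸)/mean(|H|⁴)` retention plus the floor's
in-band share), which is what the DE parameter-recovery tests compare
against.

Defaults mirror the emulated corpus geometry: 15 subjects × 3 sessions ×
(3 classes × 5 clips) = 675 trials, 62 channels, 200 Hz. Other choices:

* **Effect presets**: `strong` places ±0.5 log-variance offsets in the
  beta and gamma bands (the rhythms that carry most emotion-related
  band-power signal) on the first 30% of channels, symmetric about the
  neutral class — 0.5 nats of DE separation between the extreme classes;
  `weak` = 0.2 × strong; `null` = zeros. The presets are calibration
  knobs for testing the pipeline, not estimates of any real corpus's
  effect sizes.
* **Between-subject jitter** σ = 0.15 log-units, shared across a subject's
  trials, giving the discriminant stage genuine within-class nuisance
  scatter to suppress.
* **Clip length**: default 60 s; the benchmark runs use 4 s (four DE
  windows), which keeps the 675-trial pipeline at desk scale while the DE
  estimator noise (≈ 0.04 nats in gamma) stays far below the 0.25-nat
  class gaps.
* **Class signal lives only in variance**, because DE of a Gaussian
  depends only on variance — the generator's ground truth is analytically
  linked to the feature the method extracts.

What passing tests show: the filters, the DE estimator, the scatter
algebra, the eigen-solver, the split/metric machinery and the
no-leakage protocol are correct, and the full pipeline recovers planted
band-power class structure at realistic noise levels while staying at
chance on null data. What they do not show: performance on real EEG, which
has 1/f spectra, artifacts, nonstationarity and far subtler effects.

## Reference benchmark

`delda.benchmark.reference_benchmark` runs the full-scale comparison: 675
trials × 62 channels (strong and null presets, 4-s clips), RBF SVM, 20
stratified 70/30 splits; conditions `de` (combined band, 310 features),
`de_lda` (2 Fisher components) and `raw`. The raw baseline uses the gamma
band — the strongest single raw band — because a five-band raw
concatenation (248 000 features) makes SVM kernel evaluation the dominant
cost without changing the comparison being made. On this synthetic design
the expected ordering is de_lda ≥ de ≥ raw in accuracy, with the
2-dimensional condition fastest per split; note that raw-sample distances
do encode variance differences here, so the synthetic raw baseline is far
stronger than raw EEG baselines on real data.

## Known limitations

* EDF writing quantizes to 16 bits within a per-channel symmetric physical
  range; round-trips are exact only to that quantization step.
* LDA materializes n × n scatter matrices; the `lda`-on-raw condition is
  only tractable for short clips / few channels. The DE conditions never
  face this (n = 310).
* The generator's trials are stationary within a clip; nonstationary
  effects (habituation, drift) are out of scope.
* Five-fold CV mode reuses the same machinery but is not exercised by the
  reference benchmark.
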
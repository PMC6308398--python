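# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not
demonstrate.

## Signal conditioning

**QRS detection.** R peaks are found with a Pan–Tompkins-style chain:
zero-phase 2nd-order Butterworth band-pass 5–15 Hz, derivative,
squaring, 150-ms moving-window integration, running adaptive signal/noise
thresholds, and a 200-ms refractory period (peaks closer than that are
merged, keeping the taller). Candidate peaks are snapped to the raw-signal
maximum within ±100 ms so peak times are reported on the raw sampling
grid. A flat trace raises rather than returning an empty series.

**RR series.** Intervals are successive peak differences in ms;
intervals outside 300–2000 ms are flagged and excluded from all feature
computation (no interpolation of ectopic gaps — a window that loses too
many intervals is skipped with a warning instead).

**SKT/EDA conditioning.** Both channels are decimated from the
acquisition rate (1 kHz) to a 50-Hz working rate with a polyphase FIR
anti-alias filter, then low-pass filtered with a zero-phase 2nd-order
Butterworth at 1 Hz. Anti-aliasing always precedes decimation, and both
filters are applied forward–backward so no group delay is introduced
(the test suite checks a zero cross-correlation lag).

## Features (16 per window)

Windows are 300 s long and slide in 30-s steps; a 60-min recording
yields 111 windows of which the **last 100** are kept, on the
assumption that the target emotional state is established only some
minutes into the stimulus. Per window:

- **Time-domain HRV** (over usable RR intervals): MeanHRV = arithmetic
  mean; SDNN = sample SD (n−1); RMSSD = √(Σdᵢ²/(N−1)) over the N−1
  successive differences; NN50 = #{|dᵢ| > 50 ms}; pNN50 = NN50/N·100.
- **Frequency-domain HRV**: the tachogram is cubic-spline interpolated
  onto a uniform 4-Hz grid; PSD by Welch (256-sample Hann segments, 50%
  overlap, per-segment mean removal); band powers by trapezoidal
  integration over TP 0.003–0.4 Hz, LF 0.04–0.15 Hz, HF 0.15–0.4 Hz;
  LF/HF, nLF = LF/(LF+HF), nHF = HF/(LF+HF). The estimator choice
  (Welch vs periodogram/AR/Lomb–Scargle) is a package decision; the
  normalized powers follow the standard short-term-HRV convention. A
  window with zero HF power has an undefined LF/HF and is skipped.
- **SKT**: windowed mean and sample SD.
- **EDA**: the 50-Hz window is resampled to 32 Hz so that the level-10
  approximation band of a db3 discrete wavelet transform spans exactly
  0–0.015625 Hz (= 32/2¹¹); tonic = reconstruction from the A10
  coefficients alone (symmetric boundary extension), phasic = signal −
  tonic, which makes tonic + phasic = input an identity by
  construction. Features: phasic zero crossings (strict sign changes;
  zero samples inherit the previous sign), phasic SD, tonic mean, tonic
  SD, tonic peak-to-peak amplitude (max − min; "amplitude" is otherwise
  underdetermined).

Normalization is min-max to [0, 1] **per subject over the pooled 200
rows of both conditions, before outlier removal**, so removing rows
never changes feature scales; bounds are stored for inverse mapping. A
constant column carries no information and is pinned at 0.5 with a
warning rather than raising.

## Outlier removal

One Gaussian per emotion class (the per-subject design assumes the
feature vector is approximately normal within each induced state).
Covariances get a relative ridge λ·trace(Σ)/d on the diagonal
(λ = 10⁻⁶; absolute λ for an all-zero covariance) so they are always
invertible. Rows whose squared Mahalanobis distance from their own
class centre exceeds the χ² quantile with df = 16 are removed in a
single pass (no iterative refit). The default quantile 0.975 is a
calibration choice: under multivariate normality it removes ≈2.5% of
windows. Users who want the more aggressive cleaning sometimes seen in
practice (~15% of windows) can lower the quantile to ≈0.85. A pooled
single-Gaussian mode exists as an option but is not the default.

## Feature selection

Per-class distributions are 10-bin equal-width histograms on [0, 1]
with a Laplace pseudo-count of 1 per bin (the divergence diverges on
empty reference bins; both knobs are configurable). The divergence
direction is D(p = negative ‖ q = basic): the negative-emotion class is
the distribution of interest and the basic class the reference. All
logarithms are base 2, so divergence, entropy and information gain
share the bit unit.

The cumulative information gain of the top-k features uses the **joint
median-split partition**: each selected feature is binarized at its
pooled median, the partition cells are the nonempty joint bit patterns,
and IG(k) = H(S) − Σ_t p(t)·H(t). This makes IG(k) monotone
non-decreasing (each added feature refines the partition) and bounded
by H(S), so the curve genuinely converges; a brute-force enumeration
oracle verifies the computation at small sizes in the tests.

**Stopping rule.** With CP = ¼·(max IG − min IG), the cut k* is the
smallest k whose forward difference IG(k+1) − IG(k) has dropped below
half the maximum forward difference *and* whose IG(k) has climbed to
within CP of the curve maximum — the curve must be both flat and near
its ceiling. If no index qualifies, all features are kept; a perfectly
flat curve keeps one. The "near the ceiling" condition is this
package's reading of an ambiguous convergence criterion: the
alternative reading (IG(k) at least CP above the *minimum*) is
satisfied almost immediately on realistic curves and lets the cut fire
one feature early whenever the first ranked feature is strong, which
empirically drops genuinely informative features on planted-signal
simulations; both readings agree on flat, linear and textbook
elbow-shaped curves.

## Classifiers and evaluation

**MLP.** One hidden layer of (inputs − 1) sigmoid units (floor 1), a
sigmoid output unit, binary cross-entropy summed over the batch,
full-batch gradient descent at a fixed rate of 0.01 for exactly 2000
iterations — no momentum, no early stopping. Weights are initialized
uniform(−0.5, 0.5) from an explicit seed, so training is bit-for-bit
reproducible. The decision threshold is 0.5 with ties to the
negative-emotion class.

**LDA/QDA.** Gaussian discriminants with equal priors and the same
relative ridge as the outlier module; LDA pools the class covariances,
QDA keeps them separate. They are implemented directly (the ridge
convention matches the outlier model rather than sklearn's shrinkage
parameterizations); sklearn's QDA serves as an independent cross-check
in the tests.

**LOOCV.** n folds, fold i seeded base + i so folds are reproducible
without being weight-identical. A fold whose training labels collapse
to one class predicts the majority class with a warning. Confusion
counts aggregate over folds; metrics are accuracy, sensitivity,
specificity, PPV and NPV, with zero-denominator metrics reported as NaN
plus a warning.

**Leakage.** Normalization bounds, the outlier fit and the feature
selection are computed once on the subject's full window set and then
held fixed across LOOCV folds — matching the per-subject customization
workflow, and a known source of optimism because the held-out window
influenced the selection. A `strict_cv` mode refits the selector inside
every training fold for comparison. Neighbouring windows also overlap
by 270 s, so LOOCV folds are not independent; neither caveat can be
removed without changing the workflow being modelled.

## Synthetic recordings

The simulator emulates only what the features measure:

- **RR intervals**: i.i.d. normal, truncated to 300–2000 ms, per-condition
  mean/SD (defaults 850 ± 55 ms basic, 740 ± 40 ms negative). No
  autocorrelation, respiratory sinus arrhythmia or 1/f structure — so
  the simulated HRV *spectrum* is flat and the frequency features carry
  no programmed class signal.
- **ECG**: a Gaussian R-spike (σ = 8 ms, amplitude 1 mV) at each
  cumulative RR time plus white noise (SD 0.05 mV). No P/T waves or
  baseline wander; QRS detection on this input is deliberately easy and
  says nothing about detector performance on pathological ECG.
- **EDA**: tonic level + linear drift (4 µS basic vs 8 µS negative,
  drift 0.005 vs 0.03 µS/min) plus SCR events at Poisson times (2
  vs 8 per min) with a difference-of-exponentials kernel (rise 0.75 s,
  decay 4 s; amplitude 0.3 vs 0.6 µS) plus white noise, clipped at 0.
- **SKT**: baseline + linear drift (33.5 °C, flat vs 33.0 °C,
  −0.01 °C/min) plus low-amplitude noise.

Effect *directions* follow the established autonomic signature of fear;
effect *magnitudes* are package defaults chosen once for clear
separability, since no quantitative effect sizes exist for this
protocol. Consequently the pipeline's near-perfect LOOCV accuracy on
default simulations demonstrates correctness of the machinery
(parameter recovery, calibration, anti-leakage of the null), **not**
expected performance on human data, where reported accuracies for
comparable workflows are in the 80–95% range. The shuffled-label null
(accuracy ≈ 0.5) is the companion check that the measured separation is
carried by the labels and not by the pipeline.

All channels are synthesized at 1 kHz and conditioned by the same
preprocessing as user data. Every stochastic component draws from an
explicit seed; identical seeds give bit-identical recordings.

## Problem sizes

Tests and the acceptance script use one simulated subject per run: two
60-minute recordings (3.6 M samples per channel), 200 feature windows,
LOOCV over ≈195–200 folds with 2000 training iterations per fold.
Structural and oracle tests use shorter (5–12 min) recordings and
hand-sized inputs. These sizes were chosen to exercise the full
published geometry (111 windows → last 100 per condition) while keeping
a complete run in minutes on one core.

## Known limitations

- Single-subject, two-class design; no cross-subject pooling or transfer.
- One-pass outlier removal with a classical (non-robust) covariance:
  heavy same-direction contamination can mask itself; the tests plant
  outliers in random directions, which is the favourable case.
- The histogram KLD estimator is biased at small n and sensitive to the
  bin count; 10 bins over ~100 samples per class is a coarse but stable
  default.
- `pNN50` divides by the interval count N (not N−1), and `MeanHRV` is
  the arithmetic mean of intervals; both follow the definitions the
  rest of the formula set forces.
- The MLP's "2000 repetitions" are interpreted as full-batch epochs;
  per-sample update schedules would train a different (noisier) model.
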
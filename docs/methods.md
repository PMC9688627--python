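# Methods

## Problem setting

The pipeline classifies subjects as depressive (DEP = 0) or control
(CTL = 1) from short segments of eyes-closed resting-state EEG, using only
nonlinear complexity descriptors computed on a few electrodes. It is
organized as four stages — space–time selection, feature/classifier
selection, tuning/training, external validation — each reusable on its own.

## Preprocessing

Recordings (EDF+ or FIF, 10-20 channel names, an `eyes_closed` trigger
annotation) pass through a zero-phase filter chain at the native sampling
rate: order-4 Butterworth band-pass 0.1–120 Hz, 50 Hz notch (Q = 30),
order-4 low-pass at 90 Hz, then common average reference. The filters are
forward-backward IIR; because the 0.1 Hz edge has a multi-second impulse
response, filtering pads with up to 10 s of reflected signal so edge
transients do not smear inward (without this, a 10 s test tone retains
~0.3 of its notched energy as sidebands). An artifact-removal hook is
accepted by `filter_chain(artifact_hook=...)` and defaults to pass-through;
synthetic cohorts are artifact-free, and an ASR-style cleaner can be plugged
in for real data.

The segment of `span` seconds after the trigger is cropped, polyphase
resampled to 200 Hz, split into consecutive non-overlapping 200-sample
(1 s) windows (trailing remainder dropped; windows are half-open
`[k·200, (k+1)·200)` with 0-based indexing), and each channel row of each
window is scaled to unit L2 norm. Unit-norm scaling makes windows
scale-free, so features respond to signal *shape*, not amplitude; features
are therefore computed on the normalized windows.

## Complexity features

Six estimators, implemented from their definitions (no external feature
library) and cross-checked in the test suite against literal loop-based
oracles and analytic limits:

| feature | definition | parameters (default) | limits used as checks |
|---|---|---|---|
| PermEnt | base-2 entropy of ordinal patterns, stable-sorted ties | order 3, delay 1, /log2(3!) | monotone → 0; i.i.d. noise → 1 |
| SampEn | −ln(A/B), Chebyshev template matches, no self-matches | m = 2, r = 0.2·SD | alternating series → ~0 |
| SVDEnt | entropy of normalized singular values of the delay embedding | order 3, delay 1, /log2(3) | constant → 0; noise → ≥0.95 |
| DFA α | slope of log RMS detrended fluctuation vs log box size | boxes log-spaced 4…n/4 | white 0.5; Brownian 1.5; ramp ≥1.8 |
| SpectEnt | entropy of the Welch PSD as a distribution | nperseg min(n, 256), /log2(#bins) | tone ≤0.2; white ≈1 |
| Higuchi | −slope of log mean curve length L(k) vs log k | kmax 10 | line 1; white 2 |

Sample entropy raises a distinct "undefined" error when A or B is zero and a
degenerate-input error for constant signals (r = 0) rather than returning a
silent 0. DFA box sizes are capped at n/4 so all six estimators run at the
pipeline's 200-sample windows; at that length SampEn and DFA are
high-variance estimates, which is priced into the study design (many windows
per subject, electrode averaging) rather than hidden.

Per window, each feature is computed per electrode and arithmetically
averaged across the selected electrodes. The canonical feature order
(PermEnt, SampEnt, SVDEnt, DFA, SpectEnt, Higuchi) names the cumulative
combinations COMB0…COMB5.

## Electrode-region table

A Desikan-parcel → 10-20 electrode association table (26 regions) is
shipped as a versioned CSV resource and reproduced cell-for-cell by a test.
Nonstandard labels present in the source table (N1, N2, F9, F10) are kept
verbatim; montage matching is case-insensitive, and synthetic montages
simply never include the nonstandard labels. Two frontal regions share an
identical electrode list in the source; both entries are kept, and region
ties break lexicographically after the fewer-electrodes rule.

## Selection procedures

All three sweeps score a pipeline of standard scaling + logistic regression
(scaler fit inside each training fold) with stratified k-fold CV (k = 10 by
default; one printed account of the electrode step used k = 5, so k is a
config knob) on window-level feature vectors, seeded so folds and scores are
reproducible.

- **Span**: spans 1–17 s in steps of 2, two baseline features (Higuchi,
  SampEn) averaged over all channels. Chosen span = the smallest whose
  per-fold scores are not significantly below any larger span (two-sided
  paired t, α = 0.05; a zero-variance paired difference is a tie when
  exactly zero and decisive otherwise).
- **Region**: every region fully covered by the montage, features averaged
  over that region's electrodes at the chosen span. Chosen region = highest
  mean accuracy; any region not significantly below the top one enters a
  tie set resolved by fewer electrodes, then name.
- **Features**: the six features on the chosen electrodes are ranked by
  k-NN mutual information with the label (ties broken by feature name, so
  the ranking is invariant to column order), then cumulative prefixes
  COMB0…COMB5 are scored; the full set is kept unless a shorter prefix is
  significantly *better*.

Because 1 s windows nest across spans and electrode subsets only change an
average, all sweeps run from one per-channel feature table computed once at
the largest span — an exact reformulation, not an approximation.

**Window-level vs subject-level folds.** The default split treats windows
as exchangeable samples, which mirrors vector-level splitting but lets
windows of one subject land in both train and test folds. With strong
subject-level random effects this inflates accuracy (the classifier can
memorize subject signatures); `SelectionConfig(subject_level=True)` uses
stratified grouped folds instead. Reported near-perfect window-level
accuracies should be read with this caveat.

## Classifier suite

LR and SVM-RBF are scikit-learn pipelines behind a standard scaler. MLP
(64-32 ReLU), CNN (two Conv1D(32, k=3) + sigmoid dense), LSTM (stacked
64-64-32-32 LSTM layers → batch-norm → sigmoid dense with L2 penalty 1e-3)
and CNNGRU (Conv1D(32, k=3) → max-pool(2) → GRU(32) → flatten → sigmoid
dense) run on the package's NumPy engine: float64 throughout, Glorot
initialization, Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), binary cross-entropy,
100 epochs and batch 32 by default, 80/20 train/validation split, and a
checkpoint that restores the weights of the lowest-validation-loss epoch.
Each six-feature sample enters the sequence models as (timesteps = 6,
channels = 1) in canonical feature order — the axis convention is a package
choice, stated rather than assumed, and configurable via the feature order.
Hidden sizes are likewise package defaults (modest capacities suited to
6-dimensional inputs), all overridable. Every layer's backward pass is
verified against central-difference gradients to <1e-5 relative error, and
checkpoint save/load round-trips are bit-identical.

`compare_classifiers` evaluates all specs on identical stratified folds and
reports the fold-matched accuracies plus a symmetric paired-t p-value matrix
(NaN diagonal; NaN for zero-variance differences). Plain paired t-tests are
used deliberately — they match the emulated analysis — although fold
overlap makes them anti-conservative; no corrected resampled variant is
applied.

## Evaluation

Accuracy, precision, recall and F1 come from exact confusion-count formulas
with CTL = 1 as the positive class (switchable); zero-denominator metrics
are NaN plus an `undefined` flag. ROC/AUC uses the full threshold sweep and
trapezoid rule and is tested against a concordant-pair count (the
Mann–Whitney identity). The two-sample t utility works from group summary
statistics with pooled variance — pooling, not Welch, because the degrees
of freedom of the published contrasts it reproduces match pooling. One
published age contrast is not reproducible from its printed summaries and
one df is inconsistent with its group sizes; the t values, not the df, are
treated as the reproducible quantities, and the age contrast is excluded.

`external_validate` applies the frozen chain (training-time span,
electrodes, feature combination, trained weights — nothing refit) to new
recordings and emits a full report; it errors by name on any missing
selected electrode.

## Synthetic cohorts

Each channel is unit-variance 1/f^β noise (FFT spectral shaping of white
Gaussian noise) scaled to 10 µV RMS, plus a 10 ± 0.3 Hz sinusoid (2 µV,
random phase per channel — a modest eyes-closed alpha relative to the
broadband background), a shared per-subject colored background mixed at gain
0.3 (a crude stand-in for volume conduction that induces realistic
within-subject correlation), and 1 µV white sensor noise. Defaults: 24 CTL
+ 26 DEP subjects, 32 standard channels at 500 Hz, trigger at 1 s,
β = 1.0 everywhere except β = 1.5 at FC2/AFz/F2 in DEP subjects. The β
contrast of 0.5 was fixed once as the study condition: via
α_DFA ≈ (β+1)/2 it yields a per-window DFA gap of ~0.2 at the target
electrodes — comfortably recoverable, as a strong-biomarker scenario
should be — and the region-selection ground truth is exactly the region
whose electrode list is FC2/AFz/F2. The generator does not emulate head
geometry, artifacts (an optional blink injector exists for robustness
tests only), nonstationarity, or any calibrated DEP/CTL effect size from
real data — no quantitative effect size is published for these features —
so passing tests demonstrate that the *pipeline recovers planted structure*,
not that real depression is this easy to detect.

Spans and problem sizes in tests and the acceptance script use 20 s
recordings (19 s after the trigger, enough for the 17 s grid) and cohorts
of 40–50 subjects; these are the package's stated desk-scale study sizes.

On these cohorts the span-accuracy profile is flat — per-window class
separability does not depend on how many windows are kept — so the
smallest-non-inferior rule selects 1 s. The selection logic still
reproduces, from printed fold statistics, the published choices (15 s span;
the 3-electrode region preferred over a statistically tied 5-electrode
one), which the constructed-score unit tests check directly.

## Null control and its band

With identical class parameters the pipeline should behave at chance. The
chance band [0.35, 0.65] is asserted at the 15 s operating span, where each
stage sees ≥600 windows and the CV-accuracy sampling SD is ~0.02–0.03. At
1–3 s spans a 40-subject null cohort yields 40–120 windows, whose accuracy
estimate has SD up to ~0.11 — the band is then inside sampling noise
(Monte-Carlo: ~17% of null draws at span 1 fall outside it), so sub-span
accuracies are computed and reported but not asserted against a band
narrower than their own noise.

## Numerical choices and limitations

- Entropies use base-2 logs; normalized values are base-invariant.
- Ordinal patterns break ties by order of appearance (stable argsort).
- Template matching uses ≤ r (closed tolerance), Richman–Moorman counting.
- EDF output quantizes to 16 bits over a symmetric per-channel range using
  the same affine map readers apply to the header strings, so round-trip
  error is ≤ one quantization step; recordings must be whole seconds at an
  integer rate.
- Determinism holds for fixed seeds under single-threaded BLAS; the neural
  engine is pure NumPy float64, so results are reproducible across runs on
  the same platform.
- The pipeline's near-perfect synthetic accuracies reflect the planted
  effect size and window-level CV; neither is evidence about clinical
  performance.
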
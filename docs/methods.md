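# Methods

## Signal model of the synthetic cohort

Each simulated channel is a sum of four independent, unit-calibrated
stochastic components, scaled to 20 µV RMS:

1. **AR(1) core** with lag-one coefficient φ = exp(−1/(fs·τ)), giving an
   autocorrelation function exp(−lag/τ) with e-folding time τ (the
   "intrinsic timescale" ground truth).  Innovation variance is 1 − φ², so
   the component has unit variance and signal-to-noise ratios stay
   interpretable when components are mixed.
2. **Aperiodic 1/f^e background** (SD 0.3 relative to the AR core),
   synthesized by frequency-domain shaping of white noise with amplitude
   ∝ f^(−e/2): the expected spectrum is exact and synthesis is O(n log n).
3. **Delta-range component**: band-filtered noise centred at 1.0 Hz
   (Gaussian spectral window, 1.5 Hz bandwidth; SD 0.7–0.85 by phenotype).
   Real resting EEG carries most of its spectral density at low
   frequencies; without this term the detected theta/alpha peak would be
   the global spectrum maximum and the power-ratio measure degenerate at 1.
4. **Band-limited oscillation** (alpha or theta): white noise shaped by a
   Gaussian window of bandwidth 2 Hz around the phenotype's centre
   frequency.  Filtered noise rather than a sinusoid, so the spectral peak
   has a realistic, measurable width.

Phenotypes (defaults):

| label      | exponent e | oscillation      | osc. SD | τ (s) | delta SD |
|------------|-----------:|------------------|--------:|------:|---------:|
| control    | 1.0        | alpha, 10 Hz     | 0.8     | 0.030 | 0.70     |
| doc_alpha  | 1.3        | alpha, 9 Hz      | 0.45    | 0.055 | 0.75     |
| doc_theta  | 1.3        | theta, 5 Hz      | 0.6     | 0.038 | 0.80     |
| doc_flat   | 1.5        | none             | 0       | 0.110 | 0.85     |

The `doc_alpha` minority phenotype exists because a fraction of patients do
retain alpha peaks, and the alpha-feature classification task needs both
classes populated.  Patients are drawn 10 % alpha / 30 % theta / 60 % flat.

### Cohort-level mediation structure

Per subject, unit-variance latents are generated as x ~ N(0,1),
m = a·x + √(1−a²)·noise_sd·ε₁, y = b·m + √(1−b²)·noise_sd·ε₂ (defaults
a = 0.6, b = 0.5, noise_sd = 1), so (a, b) are the standardized path
coefficients a standard-scaled mediation estimates and the indirect effect
is a·b = 0.30 exactly.  The latents act on the physical parameters through
near-linear lognormal maps: oscillation amplitude ∝ exp(0.25·x), timescale
∝ exp(0.45·m) (lognormal correlation attenuation < 10 % over ±2 SD).  The
CRS-R-like score is clip(round(11.5 + 4.5·y), 0, 23); the n_MCS
highest-scoring patients are labelled MCS, which realizes the higher MCS
score range without adding variance orthogonal to the mediation paths.

Why the recovery check uses the latents: the EEG measurement chain is a
*confounded, attenuating* map from latents to measured features — a
stronger oscillation also *shortens* the measured ACW (the oscillation's
autocorrelation crosses zero at a quarter period), and the background power
at the peak frequency depends on τ.  Mediation on measured features
therefore estimates a smaller, seed-dependent indirect effect (observed
≈ 0.1–0.5 across cohorts); it is reported as the study-style model, while
the generator-validation model on the recorded ground-truth latents
recovers a·b unbiasedly and is the one the recovery tests assert.  The
amplitude and timescale log-sensitivities (0.25, 0.45) and the theta τ of
0.038 s were chosen by measuring these elasticities on single-phenotype
sweeps and picking an operating point where the amplitude→ACW confound is
near-neutral.

### What the generator does not model

No eye/muscle/cardiac artifacts (hence no ICA stage), no volume conduction
or electrode geometry (channels are independent realizations), no
non-stationarity, no eyes-open/closed state, no etiology. Passing tests
demonstrate that the *pipeline* recovers what the generator put in — not
that real patient EEG behaves this way.

## Pre-processing

Fixed order: downsample (FIR anti-alias, integer factors only) → band-pass
0.5–40 Hz → bad-channel detection and repair → common average reference →
clip to exactly 300 s.  The band-pass is a Hamming-window FIR of length
≈ 3·fs/low ≈ 3 periods of the lowest band edge (odd length), applied
centred on reflection-padded data: zero phase, so no group delay leaks into
the ACW estimates.  Stop-band attenuation of this design exceeds 50 dB;
pass-band ripple is far below 1 dB over 1–36 Hz.

Bad-channel rules render the usual verbal criteria numerically: flatline =
successive absolute difference below 1e−8 µV for > 5 s; correlated =
Pearson r > 0.8 with another channel (the later-indexed channel is flagged,
for determinism); burst = any 1-s window whose log RMS exceeds the
channel's median by 5 robust SDs (1.4826·MAD of log window-RMS — the log
keeps the statistic near-symmetric for narrowband signals whose envelope
fluctuates; on raw RMS, clean synthetic channels false-alarm at a few
percent).  A {drift} reason code is reserved but never populated: no
threshold is defined for low-frequency drifts.  Bad channels are replaced
by the mean of the good channels — spherical-spline interpolation needs 3-D
electrode geometry this package does not model.

## Spectral estimation and peak analysis

Welch: 3-s Hamming segments, 50 % overlap, per-segment linear detrend
(prevents DC leakage into the 0.5 Hz bin; the final partial window is
dropped, as in the standard estimator), density normalization (so the
integral of power over frequency approximates the variance — the testable
Parseval property).  Electrode spectra are averaged in linear power and
log10 is taken afterwards; analysis is restricted to the inclusive
[0.5, 40] Hz sub-grid.

Peak analysis operates on the log10 values.  Conventions: plateaus count as
one peak at their first index; prominence traces stop at a *strictly*
higher sample; width crossings are linearly interpolated and clamped to the
grid edge (with a boundary flag) if a slope leaves the grid; ties in
prominence break toward lower frequency; candidate peaks for band
classification are restricted to 3–13 Hz, theta is [3, 7.5) and alpha
[7.5, 13] (half-open at 7.5, which would otherwise belong to both).  The
power ratio is a ratio of linear powers, 10^(power − max power) ∈ (0, 1];
a ratio of the two log values (which exceeds 1 for negative logs) is
available behind `ratio_scale="log"`.  Maximum/minimum power are taken over
the full 0.5–40 Hz analysis band.

## Timescales

The ACF is the biased (1/n) estimator of the mean-removed,
variance-normalized series, computed by FFT (guarantees |ρ| ≤ 1 and
positive semidefiniteness), evaluated to a default maximum lag of 20 s —
two orders of magnitude above typical ACW values, bounding compute.
"Reaches the threshold" is pinned as the first lag with ρ ≤ threshold
(decaying ACFs approach thresholds from above; for ACW-0 this is the first
zero crossing).  ACW is computed on the full pre-processed 5-min trace (not
sub-segments); the band-pass's effect on the ACF is inherited, not
corrected.  Censored windows (threshold never reached) carry a flag, are
excluded from ROI means when uncensored channels exist, and are dropped
from group statistics.

## Inference conventions

Shapiro-Wilk gate at α = 0.05 per sample (the gate's α is a package choice);
zero-range samples count as non-normal.  All tests two-sided.  The t-test
is the classic equal-variance independent test.  CRS-R enters correlations
as Spearman-only (ordinal) and mediation as a standardized numeric outcome
— product-of-coefficients OLS with case-resampling percentile bootstrap
(n = 5000), each resample re-standardized; no structural-equation model, no
ordinal link.  BH families are one per analysis block (measure set × ROI ×
cohort side), recorded in the output tables.  Quantile splits are
rank-based with the remainder assigned to the lowest groups and ties
resolved by stable sort on (value, position): n = 95 into tertiles gives
sizes (32, 32, 31).

## Classification

Linear-kernel SVM, box constraint C = 1 (the reference analysis names
neither kernel nor regularization; "hyperparameters were optimized" is not
operationalizable), wrapped in explicit one-vs-one coding — N(N−1)/2 binary
models with vote decoding — under stratified k-fold cross-validation
(stratification protects the small minority classes; folds are reduced with
a warning when a class has fewer members than folds).  Features are
standardized inside each training fold only.  Accuracy and per-class
metrics are averaged over folds; the confusion matrix is pooled; AUC is
macro one-vs-rest computed from decision scores (undefined for the 3-class
case in the reference, pinned here).

## Pipeline and problem sizes

The orchestrated run executes seven stages (simulate, preprocess, spectral,
peaks, timescales, inference, classification) and writes CSVs with floats
at 12 significant digits, making repeated runs byte-identical.  Stages are
recomputed on each run rather than cached: a full default cohort (120
subjects × 6 channels × 5 min at 250 Hz) completes in well under two
minutes, and a content-hash cache would add invalidation complexity for no
measurable benefit at this scale.  The test suite uses this default cohort
for the qualitative replication checks and a down-scaled cohort (14
subjects, 60-s recordings) for plumbing tests.

## Known limitations

* The mean-of-good-channels repair flattens genuine spatial structure; it
  is a placeholder for geometry-aware interpolation.
* Synthetic oscillation amplitudes are calibrated to reproduce detection
  rates and orderings, not absolute published power values.
* The measured-feature mediation model inherits the confounds described
  above; its coefficients should be read qualitatively.
* Recordings shorter than the clip length are rejected rather than padded;
  non-integer downsampling factors are unsupported.
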
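# Methods

## Forward model

All response estimation reduces to the regularized normal equations

    beta = (X'X + lambda I)^(-1) X'Y

per EEG channel, with `X` built from lagged copies of one or more stimulus
features (positive lag = stimulus precedes response; out-of-range samples
zero-padded) and `X'X`, `X'Y` accumulated per trial and summed, so lagged
windows never mix samples across trial boundaries. The identity matrix is
used exactly as written — no derivative/smoothness penalty variant — and a
single lambda is shared across the feature blocks of a combined model
(per-feature lambdas exist as an option but are not used by the shipped
experiments). `lambda = 0` reduces to ordinary least squares and is solved
directly; a singular system falls back to a least-squares pseudo-solution.
As lambda grows the normalized solution converges to the cross-correlation
`X'Y`, which is how the frequency-following analyses are connected to the
regression framework.

The F0-following response is estimated as a complex cross-correlation: the
real part is the per-lag correlation coefficient of the F0-band feature
with the EEG (normalization by `n * sd(x) * sd(y)`), the imaginary part the
same for the feature's quadrature (imaginary part of its analytic signal),
and the magnitude of the trial-averaged complex function is read as the
response envelope over lags. Averaging is phase-coherent (mean of real and
imaginary parts across trials, magnitude afterwards).

Lag windows: −5.13…25.15 ms at 4096 Hz for subcortical models (125
columns per feature), −312…812 ms at 64 Hz for cortical models. Peak
windows: 5–11 ms (subcortical), 100–210 ms (cortical envelope), 50–160 ms
(relative pitch); the peak is the maximum (not the absolute extremum),
ties break to the earliest latency. Subcortical traces are read at Cz,
cortical ones as the mean of FC1, FC2, FC5, FC6, F3, F4.

## Cross-validation

The ridge parameter is selected by a three-way nested procedure: trials
split ~72/18/10% into training/validation/test; for each of 5 inner
re-splits every lambda on the grid (default 17 values log-spaced
10^-4…10^12) is fit on training trials and scored on validation trials,
using only the lags inside a fit window (47–266 ms cortical, 2.44–12.21 ms
subcortical-combined) — weights outside the window are zeroed before
predicting, which keeps the selection focused on the physiologically
plausible response while the model itself spans the full window. The best
lambda is refit on training+validation and scored on the held-out test
trials; 10 outer repeats with re-randomized splits are averaged at the
weight level. The reported `lam` of a nested-CV model is the geometric
median of the outer selections. Subcortical single-feature models use
`lambda = 0` with leave-one-trial-out cross-validation instead.

Prediction accuracy is the per-trial Pearson correlation between predicted
and observed EEG, averaged across trials; degenerate (constant)
predictions score 0 and are flagged rather than propagating NaNs.

## Feature extraction

Audio and EEG pass through the same windowed-sinc (Hamming) FIR designs so
both accrue identical group delays; the subcortical audio and EEG chains
are literally the same code path, and a test asserts their outputs are
equal on identical inputs. Filter orders follow `order = ceil(3.3 *
fs / transition_width)` rounded to even. High-pass filters are built by
spectral inversion of the complementary low-pass, which nulls DC exactly.
The filter engine exposes three application modes — `causal` (plain
one-pass), `compensated` (one-pass with the group delay removed; the
default), and `twopass` (forward-backward) — because the choice matters
for whether late response energy can leak to earlier lags; subcortical
chains default to `compensated`, the cortical envelope chain uses
`twopass`.

* broadband_rectified: anti-alias + downsample to 4096 Hz, 80 Hz
  high-pass (transition 20 Hz), half-wave rectification, first/last second
  trimmed.
* f0_band: same chain with a 240 Hz low-pass (transition 60 Hz) instead of
  rectification.
* envelope: resample to 12 kHz, 24-band 4th-order gammatone filterbank
  (ERB-spaced 100 Hz–4 kHz, scipy's FIR gammatone), half-wave
  rectification, power-law compression with exponent 0.3, band average,
  downsample 12 kHz → 512 → 64 Hz, 1 Hz high-pass + 9 Hz low-pass.
* relative_pitch: F0 tracked at 4096 Hz with a cumulative-mean-normalized
  difference function (YIN-family), candidate lags restricted to 80–240 Hz,
  harmonicity threshold 0.1 marks unvoiced frames, parabolic lag
  interpolation, one frame per 64 Hz output sample; unvoiced frames are
  linearly interpolated (edges held), the track is resampled to a uniform
  64 Hz grid and z-scored per trial. A track whose standard deviation is
  below 0.5 Hz is treated as constant (the tracker's quantization jitter is
  not pitch movement) and maps to zeros.

All features are z-scored at the trial level before entering a model.
Synthetic EEG is not additionally z-scored: correlation-based accuracy is
scale-invariant, and keeping the synthesis scale makes SNR bookkeeping
exact.

## Synthetic data

The generator reproduces the statistical structure the analyses assume,
not speech acoustics:

* F0 trajectory: Gaussian-smoothed white noise (kernel width 0.05 s),
  scaled to an excursion of ±30 Hz around 107 Hz and clipped to 80–240 Hz.
  The 0.05 s width places most of the contour's power at syllable-to-word
  rates (~66% inside 1–9 Hz), which is the premise of cortical
  relative-pitch tracking; a much smoother contour would fall below the
  cortical analysis band and make pitch tracking undetectable by design.
* carrier: band-limited pulse train — the first N harmonics of the
  instantaneous F0 with N chosen so the highest harmonic stays below
  0.45 × rate, evaluated in closed form (Dirichlet kernel) from the
  accumulated phase.
* modulator: positive envelope `1 + 0.9 m(t)` with `m` band-limited to
  1–9 Hz and peak-normalized; waveform peak-normalized to |x| ≤ 1.
* EEG: sum of feature-kernel convolutions (kernel lag 0 = simultaneity)
  placed identically on every channel, plus independent per-channel 1/f
  noise (spectrally shaped white Gaussian noise, exact target spectrum,
  standardized per channel). SNR is defined as the per-channel variance
  ratio in dB and realized exactly by construction.
* kernels: difference-of-Gaussians shapes normalized to unit maximum — a
  sharp wave-V-like kernel peaking at 7 ms over 30 ms (4096 Hz), and
  biphasic cortical kernels peaking near 140 ms (envelope) and 100 ms
  (relative pitch) over 400 ms (64 Hz). On the 64 Hz lag grid the nominal
  140/100 ms peaks land on 140.6/93.8 ms samples; recovery is judged
  against the gridded truth.
* click trains: rectangular 80 µs clicks at exactly 10 Hz with alternating
  polarity and no jitter; 5 minutes gives 3000 events. Synthetic click EEG
  convolves the *rectified* click train with the kernel (cochlear
  rectification — with alternating polarity the acoustic waveform cancels
  across epochs but the neural response must not), applies a 1.05 ms
  presentation delay rounded to 4 samples at 4096 Hz, and the averaging
  stage subtracts the nominal 1.05 ms from the lag axis; the residual
  0.07 ms sub-sample mismatch is far below the peak-latency tolerances
  used anywhere.

What the generator does not emulate: scalp topography (all channels carry
the same signal), ocular or movement artifacts, cochlear nonlinearity
beyond rectification+compression, reverberation, or real prosody and
phonetics. Consequently, passing tests demonstrate that the estimators
recover known kernels under the assumed noise model and feature
correlation structure — not that they would behave identically on real
recordings with topographic structure and non-stationary artifacts.

## Preprocessing

Re-referencing subtracts the mean of the chosen reference channels.
The subcortical EEG chain mirrors the audio chain (anti-alias + decimate
to 4096 Hz, 80 Hz high-pass, optional 240 Hz low-pass for the F0 variant,
1 s edge trim). The cortical chain resamples to 64 Hz (30 Hz anti-alias),
high-passes at 0.5 Hz and band-passes 1–9 Hz. Line noise is removed by
zeroing narrow DFT bins (50/100/150 Hz, bandwidths 1/2/3 Hz). Click-ABR
averaging epochs at event onsets, rejects any epoch whose absolute voltage
exceeds 20 µV (applied to the analyzed channel over the full epoch
window), divides each surviving epoch by its variance, and averages.
Artifact rejection operates on the conditioned signal; variance weighting
uses the full epoch window.

## Simulation experiments

SNR sweep: per run, 20 trials of 10 s are generated; the feature pair and
an additional unit-variance white Gaussian driver are convolved with their
kernels; 1/f noise is added at each SNR on the grid (−30…0 dB in 5 dB
steps by default). Individual, combined, and feature+Gaussian models are
fit with a jointly selected lambda (9-value grid 10^-4…10^12, selected on
a validation split, refit on training+validation, scored on held-out test
trials). The improvement is the combined model's test accuracy minus the
best individual model's; the uncorrelated bound is the same quantity from
a parallel simulation in which the second driver is the white Gaussian,
power-matched so its kernel-convolved contribution carries the same
variance as the feature it replaces (without power matching the "bound"
is not an upper bound, because an autocorrelated feature concentrates its
power where the kernel has gain). Subcortical mode draws both features
from the same synthetic speech (r ≈ 0.9); cortical mode uses the envelope
and an independently wandering F0 (|r| ≈ 0.05–0.3). The sweep synthesizes
subcortical stimuli at 8192 Hz and cortical ones at 16384 Hz (the
envelope chain needs ≥ 12 kHz).

For speed, the normal equations of lagged designs are computed directly
from the raw series via FFT cross-correlations plus cumulative-sum edge
corrections — algebraically identical to the explicit design-matrix
products (a unit test holds them equal to ~1e-15) — and predictions are
formed by convolution with the weight vector. Because the synthesized EEG
is `signal + sigma * noise`, fitted weights and predictions are linear in
sigma, so each (model, lambda) pair is solved once for the signal and
noise components and every SNR on the grid is scored from the same two
solves.

Regularization × autocorrelation: white or low-passed Gaussian features
(cutoffs 1.0/0.1/0.02 of Nyquist) are convolved with the wave-V-like
kernel, noise is added at 0 dB, and the kernel is re-estimated at each
lambda. Reported per (level, lambda): peak-latency error, full width at
half maximum relative to the true kernel (flagged when a half-maximum
crossing is missing), and the RMS error between unit-norm estimated and
true kernels (sign-aligned; unit-norm because large-lambda estimates are
arbitrarily scaled).

End-to-end pipeline: one shared stimulus/feature set (as in a real
experiment where all subjects hear the same audiobook), per-subject EEG at
−15 dB (subcortical, Cz) and −5 dB (cortical, six frontal channels + Cz),
per-subject click EEG (5 µV noise floor, −15 dB, five injected 100 µV
artifact epochs), then: LOO OLS TRF on the broadband feature, complex
cross-correlation on the F0 band, ABR averaging, nested-CV models for
envelope/pitch/combined, peak extraction, paired-permutation model
comparison, and across-subject one-tailed Pearson correlations with
Benjamini–Yekutieli correction. Every stage is seeded; a fixed
configuration+seed reproduces byte-identical TSV outputs.

Default problem sizes (20 trials × 10 s; 20 sweep runs; 10 synthetic
subjects) are desk-scale stand-ins for a full study (which would be, e.g.,
36 × 50 s trials); they were chosen once as the smallest sizes at which
the qualitative patterns are stable across seeds.

## Statistics

Paired contrasts use sign-flip permutation tests on per-subject
differences (statistic: mean difference). All 2^n sign patterns are
enumerated when 2^n ≤ 65536, making the p-value exact; otherwise 10,000
random flips with the add-one correction `(1 + hits) / (1 + n_perm)`.
One-tailed Pearson p-values come from the closed-form t transform with
n−2 degrees of freedom; the test direction must be given explicitly.
Families of p-values are adjusted with Benjamini–Yekutieli step-up
(`c(m) = sum 1/i`), valid under arbitrary dependence, via statsmodels.
Model comparison computes per-subject improvements (combined minus the
subject's best individual model) before any aggregation, mirroring the
paired test.

## Numerical choices and degenerate inputs

* Solves use `numpy.linalg.solve` with a least-squares fallback on
  singularity; `lambda = 0` and `lambda = 1e-12` agree to float precision.
* Z-scoring maps constant inputs to zeros instead of dividing by zero.
* Zero-variance features are rejected with `ValueError` in the
  cross-correlation; a zero EEG trace returns an all-zero response.
* Pearson scoring returns 0 with a flag for constant predictions.
* Tie-breaks: peak extraction takes the earliest maximum; lambda selection
  takes the first grid value at the maximal validation score.
* Seeds: every public generator/experiment takes an integer seed and
  derives independent substreams via `numpy.random.SeedSequence`; equal
  seeds give bit-identical outputs.

## Known limitations

* Single-channel simulations cannot probe topography-dependent analyses;
  the frontal-6 aggregate is exercised mechanically, not physiologically.
* The YIN-family tracker is evaluated on clean synthetic speech; its
  unvoiced-detection threshold (0.1) was declared, not tuned on real
  speech.
* The uncorrelated-feature bound is defined under power matching; other
  definitions (e.g., unit-variance driver without matching) change its
  scale at low SNR.
* The causal/compensated filter switch changes absolute response latencies
  by up to half a filter length if misused; mixed modes between audio and
  EEG chains are not guarded against beyond the symmetry test.
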
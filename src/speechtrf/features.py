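"""Stimulus feature extraction.

Four predictor time series are extracted from the speech waveform, two per
analysis family:

subcortical (4096 Hz)
    * ``broadband_rectified`` — downsample, 80 Hz high-pass, half-wave
      rectification (transient/broadband energy; drives ABR-like responses);
    * ``f0_band`` — same chain but band-limited 80–240 Hz instead of
      rectified (the fundamental-frequency fine structure).

cortical (64 Hz)
    * ``envelope`` — 24-band ERB-spaced gammatone filterbank (100 Hz–4 kHz),
      half-wave rectification, power-law compression (exponent 0.3), band
      average, downsampling, 1–9 Hz band-pass;
    * ``relative_pitch`` — per-frame F0 track (difference-function method
      constrained to 80–240 Hz), interpolated over unvoiced frames and
      z-scored, so it carries the pitch *contour* rather than absolute
      periodicity.

Audio and EEG are conditioned with the same filter designs (see
:mod:`speechtrf.filters`) so that features and neural responses share group
delays. Subcortical chains trim the first and last second to discard filter
transients.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal

from .containers import AudioSignal, FeatureSeries
from .filters import apply_fir, design_fir, fir_filter, resample_to

__all__ = [
    "SUBCORTICAL_RATE",
    "CORTICAL_RATE",
    "extract_broadband_rectified",
    "extract_f0_bandpassed",
    "extract_envelope",
    "extract_relative_pitch",
    "zscore_trial",
    "erb_space",
    "yin_track",
]

SUBCORTICAL_RATE = 4096.0
CORTICAL_RATE = 64.0

# anti-alias / band-edge settings used by both audio and EEG chains
AA_4096 = dict(aa_cutoff=1638.4, aa_transition=409.6)
HIGHPASS_80 = dict(cutoff=80.0, transition=20.0)
LOWPASS_240 = dict(cutoff=240.0, transition=60.0)
TRIM_SECONDS = 1.0


def _check_audio(audio: AudioSignal, min_rate: float):
    if audio.rate < min_rate:
        raise ValueError(f"audio rate {audio.rate} Hz below required {min_rate} Hz")


def _trim(x: np.ndarray, rate: float, trim: float) -> np.ndarray:
    k = int(round(trim * rate))
    if x.size - 2 * k <= 0:
        raise ValueError("trial too short: nothing left after trimming edges")
    return x[k:x.size - k] if k else x


def _to_subcortical_rate(x: np.ndarray, rate: float, mode: str) -> np.ndarray:
    return resample_to(x, rate, SUBCORTICAL_RATE, mode=mode, **AA_4096)


def extract_broadband_rectified(audio: AudioSignal, mode: str = "compensated",
                                trim: float = TRIM_SECONDS) -> FeatureSeries:
    """Half-wave rectified, 80 Hz high-passed broadband feature at 4096 Hz."""
    _check_audio(audio, 8192.0)
    x = _to_subcortical_rate(audio.samples, audio.rate, mode)
    x = fir_filter(x, SUBCORTICAL_RATE, HIGHPASS_80["cutoff"], "highpass",
                   transition=HIGHPASS_80["transition"], mode=mode)
    x = np.maximum(x, 0.0)
    x = _trim(x, SUBCORTICAL_RATE, trim)
    return FeatureSeries(x, SUBCORTICAL_RATE, label="broadband_rectified")


def extract_f0_bandpassed(audio: AudioSignal, mode: str = "compensated",
                          trim: float = TRIM_SECONDS) -> FeatureSeries:
    """80–240 Hz band-limited (F0-band) feature at 4096 Hz, no rectification."""
    _check_audio(audio, 8192.0)
    x = _to_subcortical_rate(audio.samples, audio.rate, mode)
    x = fir_filter(x, SUBCORTICAL_RATE, HIGHPASS_80["cutoff"], "highpass",
                   transition=HIGHPASS_80["transition"], mode=mode)
    x = fir_filter(x, SUBCORTICAL_RATE, LOWPASS_240["cutoff"], "lowpass",
                   transition=LOWPASS_240["transition"], mode=mode)
    x = _trim(x, SUBCORTICAL_RATE, trim)
    return FeatureSeries(x, SUBCORTICAL_RATE, label="f0_band")


# ---------------------------------------------------------------------------
# gammatone envelope
# ---------------------------------------------------------------------------

_ERB_Q = 21.4
_ERB_MIN_BW = 0.00437


def erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """n center frequencies equally spaced on the ERB-number scale."""
    def to_erb(f):
        return _ERB_Q * np.log10(_ERB_MIN_BW * f + 1.0)

    def from_erb(e):
        return (10.0 ** (e / _ERB_Q) - 1.0) / _ERB_MIN_BW

    return from_erb(np.linspace(to_erb(f_lo), to_erb(f_hi), n))


def extract_envelope(audio: AudioSignal, band_pass: bool = True,
                     n_bands: int = 24, f_lo: float = 100.0,
                     f_hi: float = 4000.0) -> FeatureSeries:
    """Compressed gammatone envelope at 64 Hz, band-passed 1–9 Hz.

    Chain: resample to 12 kHz -> 24-band 4th-order gammatone filterbank
    (ERB-spaced 100 Hz–4 kHz) -> half-wave rectify -> compress with exponent
    0.3 -> average bands -> downsample 12 kHz -> 512 Hz -> 64 Hz -> 1 Hz
    high-pass + 9 Hz low-pass (two-pass). ``band_pass=False`` returns the
    envelope before the final band-pass (useful for checking the
    compression law).
    """
    _check_audio(audio, 12000.0)
    fs = 12000.0
    x = resample_to(audio.samples, audio.rate, fs, aa_cutoff=6000.0 if audio.rate > 13500 else None,
                    aa_transition=1485.0, mode="twopass")
    if x.size < int(0.05 * fs):
        raise ValueError("audio shorter than the filterbank startup length")
    env = np.zeros_like(x)
    for fc in erb_space(f_lo, f_hi, n_bands):
        b, a = sp_signal.gammatone(fc, "fir", fs=fs)
        band = apply_fir(x, b, mode="causal")
        env += np.maximum(band, 0.0) ** 0.3
    env /= n_bands
    env = resample_to(env, fs, 512.0, aa_cutoff=256.0, aa_transition=64.0,
                      mode="twopass")
    env = resample_to(env, 512.0, 64.0, aa_cutoff=30.0, aa_transition=7.5,
                      mode="twopass")
    if band_pass:
        env = fir_filter(env, 64.0, 1.0, "highpass", order=106, mode="twopass")
        env = fir_filter(env, 64.0, 9.0, "lowpass", order=94, mode="twopass")
    return FeatureSeries(env, CORTICAL_RATE, label="envelope")


# ---------------------------------------------------------------------------
# F0 tracking (difference-function method)
# ---------------------------------------------------------------------------

def yin_track(x: np.ndarray, fs: float, fmin: float = 80.0, fmax: float = 240.0,
              frame_len: float = 0.040, hop: int | None = None,
              threshold: float = 0.1):
    """Per-frame F0 via the cumulative-mean-normalized difference function.

    For each frame the difference function ``d(tau) = sum_j (x_j -
    x_{j+tau})^2`` is normalized by its running mean; the first lag whose
    normalized value drops below ``threshold`` (else the global minimum) is
    refined by parabolic interpolation. Frames with no dip below the
    threshold are marked unvoiced.

    Returns ``(f0, voiced, frame_centers_s)``.
    """
    x = np.asarray(x, dtype=np.float64)
    tau_min = max(2, int(np.floor(fs / fmax)))
    tau_max = int(np.ceil(fs / fmin))
    w = int(round(frame_len * fs))
    if w <= tau_max:
        w = tau_max + 2
    if hop is None:
        hop = max(1, int(round(fs / 64.0)))
    span = w + tau_max
    if x.size < span:
        raise ValueError("signal shorter than one analysis frame")
    starts = np.arange(0, x.size - span + 1, hop)
    frames = np.lib.stride_tricks.sliding_window_view(x, span)[starts]
    n_frames = frames.shape[0]
    d = np.empty((n_frames, tau_max + 1))
    d[:, 0] = 0.0
    base = frames[:, :w]
    for tau in range(1, tau_max + 1):
        diff = base - frames[:, tau:tau + w]
        d[:, tau] = np.einsum("ij,ij->i", diff, diff)
    cum = np.cumsum(d[:, 1:], axis=1)
    dn = np.ones_like(d)
    taus = np.arange(1, tau_max + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dn[:, 1:] = np.where(cum > 0, d[:, 1:] * taus / cum, 1.0)

    f0 = np.zeros(n_frames)
    voiced = np.zeros(n_frames, dtype=bool)
    region = dn[:, tau_min:tau_max + 1]
    below = region < threshold
    any_below = below.any(axis=1)
    first_dip = np.argmax(below, axis=1)
    global_min = np.argmin(region, axis=1)
    pick = np.where(any_below, first_dip, global_min) + tau_min
    for i in range(n_frames):
        tau = int(pick[i])
        if any_below[i]:
            # descend to the local minimum of the dip
            while tau + 1 <= tau_max and dn[i, tau + 1] < dn[i, tau]:
                tau += 1
        t_hat = float(tau)
        if 1 <= tau < tau_max:
            a, b, c = dn[i, tau - 1], dn[i, tau], dn[i, tau + 1]
            denom = a - 2 * b + c
            if abs(denom) > 1e-12:
                t_hat = tau + 0.5 * (a - c) / denom
        f0[i] = np.clip(fs / t_hat, fmin, fmax)
        voiced[i] = any_below[i]
    centers = (starts + w / 2.0) / fs
    return f0, voiced, centers


def extract_relative_pitch(audio: AudioSignal, threshold: float = 0.1) -> FeatureSeries:
    """Z-scored F0 contour at 64 Hz (relative pitch).

    The audio is brought to 4096 Hz, the F0 is tracked per frame within
    80–240 Hz, unvoiced frames are linearly interpolated (edges held), the
    track is interpolated onto a uniform 64 Hz grid and z-scored per trial.
    A fully unvoiced trial raises ``ValueError``.
    """
    fs = SUBCORTICAL_RATE
    x = resample_to(audio.samples, audio.rate, fs, mode="twopass", **AA_4096) \
        if audio.rate != fs else audio.samples
    f0, voiced, centers = yin_track(x, fs, threshold=threshold)
    if not voiced.any():
        raise ValueError("no voiced frames: cannot estimate F0")
    if not voiced.all():
        idx = np.flatnonzero(voiced)
        f0 = np.interp(np.arange(f0.size), idx, f0[idx])
    n_out = int(round(audio.samples.size / audio.rate * CORTICAL_RATE))
    grid = np.arange(n_out) / CORTICAL_RATE
    track = np.interp(grid, centers, f0)
    if track.std() < 0.5:
        # sub-semitone jitter at the tracker's resolution is not pitch
        # movement; treat the trial as constant-F0 (guarded z-score -> 0)
        return FeatureSeries(np.zeros(n_out), CORTICAL_RATE,
                             label="relative_pitch", zscored=True)
    series = FeatureSeries(track, CORTICAL_RATE, label="relative_pitch")
    return zscore_trial(series)


def zscore_trial(series):
    """Z-score a series (mean 0, variance 1); constants map to zeros.

    Accepts a :class:`FeatureSeries` (returned with ``zscored=True``) or a
    plain array. Idempotent up to float rounding.
    """
    if isinstance(series, FeatureSeries):
        z = zscore_trial(series.samples)
        return FeatureSeries(z, series.rate, label=series.label, zscored=True)
    x = np.asarray(series, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least two samples to z-score")
    sd = x.std()
    if sd < 1e-15 * max(1.0, np.abs(x).max()):
        return np.zeros_like(x)
    return (x - x.mean()) / sd
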
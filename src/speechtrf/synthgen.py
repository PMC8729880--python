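"""Synthetic stimuli, ground-truth response kernels, and simulated EEG.

The study design this package targets — running-speech EEG with both
subcortical (ABR-like, ~7 ms) and cortical (~100–140 ms) response components
— uses human data that cannot be redistributed, so every analysis here is
exercised against synthetic sessions with known ground truth:

* a speech-like stimulus: a band-limited pulse-train carrier at a smoothly
  wandering fundamental frequency (F0, confined to 80–240 Hz, male-like mean
  around 107 Hz), amplitude-modulated by a slow positive envelope whose
  fluctuations live in the 1–9 Hz band;
* click trains with alternating polarity for conventional ABR averaging;
* EEG formed by convolving stimulus features with predetermined response
  kernels and adding 1/f ("EEG-shaped") noise at a controlled SNR.

SNR is defined as the per-channel variance ratio in dB,
``10*log10(var(signal)/var(noise))``. All randomness flows from explicit
integer seeds through ``numpy.random.SeedSequence`` so that any function
called twice with the same seed returns bit-identical output.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter1d

from .containers import (
    AudioSignal,
    EEGRecording,
    FeatureSeries,
    GroundTruthKernel,
    SyntheticSession,
)

__all__ = [
    "make_f0_trajectory",
    "make_speech_like_stimulus",
    "make_click_train",
    "make_pink_noise",
    "synthesize_eeg",
    "make_feature_pair",
    "default_subcortical_kernel",
    "default_cortical_envelope_kernel",
    "default_cortical_pitch_kernel",
    "make_session",
]

F0_RANGE = (80.0, 240.0)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(seed))


# ---------------------------------------------------------------------------
# stimulus generation
# ---------------------------------------------------------------------------

def make_f0_trajectory(duration: float, rate: float, mean_f0: float = 107.0,
                       excursion: float = 30.0, smoothness: float = 0.05,
                       seed: int = 0) -> FeatureSeries:
    """Smooth random instantaneous-F0 series in Hz, confined to 80–240 Hz.

    A Gaussian-smoothed white-noise walk (kernel width ``smoothness``
    seconds) is scaled so that its standard deviation is ``excursion / 3``
    and hard-limited to ``mean_f0 +/- excursion``. ``excursion = 0`` yields a
    constant trajectory.
    """
    lo, hi = F0_RANGE
    if not (lo <= mean_f0 <= hi):
        raise ValueError(f"mean_f0 must lie in [{lo}, {hi}] Hz")
    if excursion < 0:
        raise ValueError("excursion must be >= 0")
    n = int(round(duration * rate))
    if n == 0:
        return FeatureSeries(np.empty(0), rate, label="f0_trajectory")
    if excursion == 0:
        return FeatureSeries(np.full(n, mean_f0), rate, label="f0_trajectory")
    rng = _rng(seed)
    walk = rng.standard_normal(n)
    walk = gaussian_filter1d(walk, sigma=max(smoothness * rate, 1e-9), mode="reflect")
    sd = walk.std()
    if sd > 0:
        walk = walk / sd * (excursion / 3.0)
    dev = np.clip(walk, -excursion, excursion)
    f0 = np.clip(mean_f0 + dev, lo, hi)
    if f0.min() < lo or f0.max() > hi:  # cannot happen after clipping
        raise ValueError("trajectory left the 80-240 Hz range")
    return FeatureSeries(f0, rate, label="f0_trajectory")


def _dirichlet_harmonic_sum(phase: np.ndarray, n_harm: int) -> np.ndarray:
    """sum_{k=1..N} cos(k * phase), evaluated in closed form."""
    half = phase / 2.0
    s = np.sin(half)
    num = np.sin(n_harm * half) * np.cos((n_harm + 1) * half)
    out = np.empty_like(phase)
    small = np.abs(s) < 1e-8
    np.divide(num, s, out=out, where=~small)
    out[small] = float(n_harm)
    return out


def make_speech_like_stimulus(f0_trajectory: FeatureSeries,
                              env_rate_band=(1.0, 9.0), rate: float = 16384.0,
                              seed: int = 0, mod_depth: float = 0.9) -> AudioSignal:
    """Pulse-train carrier at the instantaneous F0, slowly amplitude-modulated.

    The carrier holds the first N harmonics of the instantaneous F0 with
    ``N * max(F0) < 0.45 * rate``; the modulator is a positive envelope
    ``1 + mod_depth * m(t)`` with ``m`` band-limited to ``env_rate_band``
    and peak-normalized, so the output envelope stays positive. The waveform
    is peak-normalized to ``|x| <= 1``.
    """
    if rate < 4 * F0_RANGE[1]:
        raise ValueError("rate must be at least 4 x 240 Hz")
    n = int(round(f0_trajectory.samples.size / f0_trajectory.rate * rate))
    if n == 0:
        return AudioSignal(np.empty(0), rate)
    t = np.arange(n) / rate
    t_in = np.arange(f0_trajectory.samples.size) / f0_trajectory.rate
    f0 = np.interp(t, t_in, f0_trajectory.samples)
    if np.any(f0 < F0_RANGE[0] - 1e-9) or np.any(f0 > F0_RANGE[1] + 1e-9):
        raise ValueError("F0 trajectory leaves the 80-240 Hz range")
    n_harm = max(1, int(np.floor(0.45 * rate / f0.max())))
    phase = 2.0 * np.pi * np.cumsum(f0) / rate
    carrier = _dirichlet_harmonic_sum(phase, n_harm)

    # slow positive modulator, synthesized at a low rate and interpolated up
    lo_rate = 128.0
    n_lo = max(int(round(n / rate * lo_rate)), 64)
    rng = _rng(seed)
    m = rng.standard_normal(n_lo)
    band = np.asarray(env_rate_band, dtype=float)
    from .filters import fir_filter
    m = fir_filter(m, lo_rate, band, btype="bandpass",
                   transition=max(band[0], 0.5), mode="twopass")
    peak = np.max(np.abs(m))
    if peak > 0:
        m = m / peak
    envelope = 1.0 + mod_depth * np.interp(t, np.arange(n_lo) / lo_rate, m)
    x = carrier * envelope
    amax = np.max(np.abs(x))
    if amax > 0:
        x = x / amax
    return AudioSignal(x, rate)


def make_click_train(click_rate: float = 10.0, click_dur: float = 80e-6,
                     rate: float = 16384.0, duration: float = 300.0):
    """Alternating-polarity rectangular click train with exact spacing.

    Returns ``(AudioSignal, event_times)`` where ``event_times`` lists click
    onsets in seconds. No jitter is applied; polarity alternates +1/-1 so the
    acoustic waveform sums to zero over an even number of clicks.
    """
    if click_dur < 1.0 / rate:
        raise ValueError("sampling rate too low to represent click_dur")
    n = int(round(duration * rate))
    n_events = int(np.floor(duration * click_rate))
    dur_samples = max(1, int(round(click_dur * rate)))
    x = np.zeros(n)
    onsets = np.arange(n_events) / click_rate
    for k, t0 in enumerate(onsets):
        i0 = int(round(t0 * rate))
        x[i0:i0 + dur_samples] = 1.0 if k % 2 == 0 else -1.0
    return AudioSignal(x, rate), onsets


# ---------------------------------------------------------------------------
# noise and EEG synthesis
# ---------------------------------------------------------------------------

def make_pink_noise(n_samples: int, n_channels: int = 1, exponent: float = 1.0,
                    seed: int = 0) -> np.ndarray:
    """Channels x samples noise with power spectral density ~ 1/f**exponent.

    Built by spectrally shaping white Gaussian noise (amplitude scaled by
    ``f**(-exponent/2)``, DC removed); each channel is independent and
    standardized to zero mean, unit variance. ``exponent = 0`` gives white
    noise.
    """
    if n_samples <= 64:
        raise ValueError("n_samples must exceed 64")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = _rng(seed)
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _convolve_kernel(feature: np.ndarray, kernel: GroundTruthKernel,
                     rate: float) -> np.ndarray:
    """Convolve a feature with a kernel, lag 0 meaning simultaneity."""
    if abs(kernel.rate - rate) > 1e-6 * rate:
        raise ValueError("kernel rate must match feature rate")
    n = feature.size
    if kernel.amplitude.size > n:
        raise ValueError("kernel longer than trial")
    offset = int(round(kernel.lags[0] * rate))
    full = sp_signal.fftconvolve(feature, kernel.amplitude)
    out = np.zeros(n)
    # y[t] = full[t - offset]
    src_lo = max(0, -offset)
    dst_lo = max(0, offset)
    m = min(n - dst_lo, full.size - src_lo)
    if m > 0:
        out[dst_lo:dst_lo + m] = full[src_lo:src_lo + m]
    return out


def synthesize_eeg(features, kernels, snr_db: float, n_channels: int = 1,
                   seed: int = 0, channel_labels=None,
                   noise_exponent: float = 1.0) -> EEGRecording:
    """Single-trial EEG: sum of feature (x) kernel convolutions plus 1/f noise.

    One kernel per feature; the summed convolution is placed identically on
    every channel, and independent pink noise is added per channel, scaled so
    ``10*log10(var(signal)/var(noise)) = snr_db``. ``snr_db = inf`` disables
    the noise.
    """
    if len(features) != len(kernels):
        raise ValueError("need exactly one kernel per feature")
    rates = {f.rate for f in features}
    if len(rates) != 1:
        raise ValueError("features must share the sampling rate")
    rate = rates.pop()
    lengths = {f.samples.size for f in features}
    if len(lengths) != 1:
        raise ValueError("features must share length")
    sig = np.zeros(lengths.pop())
    for f, k in zip(features, kernels):
        sig += _convolve_kernel(f.samples, k, rate)
    sig_var = sig.var()
    if sig_var == 0:
        raise ValueError("synthesized signal has zero variance")
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_channels)]
    if np.isinf(snr_db):
        data = np.tile(sig, (n_channels, 1))
    else:
        noise = make_pink_noise(sig.size, n_channels, exponent=noise_exponent,
                                seed=np.random.SeedSequence((seed, 0x5EED)).entropy)
        sigma = np.sqrt(sig_var / 10.0 ** (snr_db / 10.0))
        data = sig[None, :] + sigma * noise
    return EEGRecording([data], rate, channel_labels, reference="synthetic")


def make_feature_pair(n_samples: int, rate: float, target_corr: float,
                      seed: int = 0):
    """Two zero-mean unit-variance series with a controlled Pearson correlation.

    The second series mixes a shared and an independent component; the
    independent component is orthogonalized against the first series, so the
    empirical correlation equals ``target_corr`` exactly (up to float error).
    """
    if not -1.0 <= target_corr <= 1.0:
        raise ValueError("target_corr must lie in [-1, 1]")
    rng = _rng(seed)
    z1 = rng.standard_normal(n_samples)
    z2 = rng.standard_normal(n_samples)
    z1 = (z1 - z1.mean()) / z1.std()
    z2 = z2 - z2.mean()
    z2 -= (z2 @ z1) / (z1 @ z1) * z1  # empirical orthogonalization
    z2 /= z2.std()
    y = target_corr * z1 + np.sqrt(1.0 - target_corr ** 2) * z2
    if abs(target_corr) < 1.0:
        y = (y - y.mean()) / y.std()
    return (FeatureSeries(z1, rate, label="pair_a"),
            FeatureSeries(y, rate, label="pair_b"))


# ---------------------------------------------------------------------------
# ground-truth kernels
# ---------------------------------------------------------------------------

def _gauss(t, mu, sigma):
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _peaked_kernel(rate, duration, pos_mu, pos_sigma, neg_mu, neg_sigma,
                   neg_gain, label):
    lags = np.arange(int(round(duration * rate))) / rate
    amp = _gauss(lags, pos_mu, pos_sigma) - neg_gain * _gauss(lags, neg_mu, neg_sigma)
    # pin the maximum exactly onto the nominal positive peak
    amp /= amp.max()
    return GroundTruthKernel(lags, amp, label=label)


def default_subcortical_kernel(rate: float = 4096.0) -> GroundTruthKernel:
    """Wave-V-like kernel: sharp positive peak at 7 ms, shallow trailing trough."""
    return _peaked_kernel(rate, 0.030, 7e-3, 0.8e-3, 10e-3, 2.0e-3, 0.5,
                          "subcortical")


def default_cortical_envelope_kernel(rate: float = 64.0) -> GroundTruthKernel:
    """Biphasic envelope-tracking kernel peaking near 140 ms."""
    return _peaked_kernel(rate, 0.400, 0.140, 0.030, 0.240, 0.045, 0.6,
                          "cortical_envelope")


def default_cortical_pitch_kernel(rate: float = 64.0) -> GroundTruthKernel:
    """Biphasic relative-pitch kernel peaking near 100 ms."""
    return _peaked_kernel(rate, 0.400, 0.100, 0.025, 0.180, 0.040, 0.5,
                          "cortical_pitch")


# ---------------------------------------------------------------------------
# full sessions
# ---------------------------------------------------------------------------

SUBCORTICAL_LABELS = ["Cz"]
CORTICAL_LABELS = ["FC1", "FC2", "FC5", "FC6", "F3", "F4", "Cz"]


def make_session(mode: str = "subcortical", n_trials: int = 20,
                 trial_duration: float = 10.0, snr_db: float = -15.0,
                 seed: int = 0, stimulus_rate: float = 16384.0,
                 mean_f0: float = 107.0, excursion: float = 30.0,
                 channel_labels=None, kernels=None) -> SyntheticSession:
    """Generate a trial-segmented synthetic session with known kernels.

    ``mode`` selects the analysis family the session is built for:

    * ``"subcortical"``: per trial, a speech-like stimulus is synthesized,
      the broadband-rectified feature (4096 Hz) is extracted and convolved
      with a wave-V-like kernel; EEG lives at 4096 Hz.
    * ``"cortical"``: the 1–9 Hz gammatone envelope and the relative-pitch
      track (both 64 Hz) each drive their own kernel; EEG lives at 64 Hz.
      F0 wanders independently of the amplitude modulator, so the two
      features are close to orthogonal.

    Trial lengths follow the feature chains (the subcortical chain trims one
    second from each end). ``seed`` fully determines all content.
    """
    from . import features as feat

    if mode not in ("subcortical", "cortical"):
        raise ValueError("mode must be 'subcortical' or 'cortical'")
    if channel_labels is None:
        channel_labels = list(SUBCORTICAL_LABELS if mode == "subcortical"
                              else CORTICAL_LABELS)
    ss = np.random.SeedSequence((int(seed), 0xA11D10))
    children = ss.spawn(n_trials)

    audio, eeg_trials = [], []
    feature_store: dict[str, list] = {}
    if kernels is None:
        if mode == "subcortical":
            kernels = [default_subcortical_kernel()]
        else:
            kernels = [default_cortical_envelope_kernel(),
                       default_cortical_pitch_kernel()]

    for i, child in enumerate(children):
        sub = child.generate_state(4)
        f0 = make_f0_trajectory(trial_duration, 64.0, mean_f0=mean_f0,
                                excursion=excursion, seed=int(sub[0]))
        stim = make_speech_like_stimulus(f0, rate=stimulus_rate, seed=int(sub[1]))
        audio.append(stim)
        if mode == "subcortical":
            trial_feats = [feat.zscore_trial(feat.extract_broadband_rectified(stim))]
        else:
            trial_feats = [feat.zscore_trial(feat.extract_envelope(stim)),
                           feat.extract_relative_pitch(stim)]
        rec = synthesize_eeg(trial_feats, kernels, snr_db,
                             n_channels=len(channel_labels), seed=int(sub[2]),
                             channel_labels=channel_labels)
        eeg_trials.append(rec.trials[0])
        for f in trial_feats:
            feature_store.setdefault(f.label, []).append(f)

    rate = kernels[0].rate
    eeg = EEGRecording(eeg_trials, rate, channel_labels, reference="synthetic")
    return SyntheticSession(audio=audio, eeg=eeg, features=feature_store,
                            kernels=list(kernels), snr_db=snr_db, seed=int(seed))
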
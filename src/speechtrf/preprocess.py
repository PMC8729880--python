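"""EEG conditioning chains for subcortical, cortical, and click-ABR analyses.

The EEG chains intentionally mirror the audio feature chains filter-for-
filter (same windowed-sinc designs, same application mode), so that the
stimulus feature and the neural response accrue identical group delays:
applying the subcortical chain to a copy of the audio and to an EEG trace
equal to that audio yields identical outputs.
"""

from __future__ import annotations

import numpy as np

from .containers import ABRWaveform, EEGRecording
from .features import AA_4096, HIGHPASS_80, LOWPASS_240, SUBCORTICAL_RATE, TRIM_SECONDS
from .filters import fir_filter, resample_to

__all__ = [
    "rereference",
    "subcortical_chain",
    "cortical_chain",
    "linenoise_filter",
    "epoch_average_abr",
]


def rereference(eeg: EEGRecording, ref_labels) -> EEGRecording:
    """Subtract the mean of the reference channels from every channel."""
    if isinstance(ref_labels, str):
        ref_labels = [ref_labels]
    idx = [eeg.channel_index(l) for l in ref_labels]
    trials = []
    for t in eeg.trials:
        ref = t[idx].mean(axis=0)
        trials.append(t - ref[None, :])
    return EEGRecording(trials, eeg.rate, eeg.channel_labels,
                        reference="+".join(ref_labels))


def subcortical_chain(eeg: EEGRecording, f0_variant: bool = False,
                      mode: str = "compensated",
                      trim: float = TRIM_SECONDS) -> EEGRecording:
    """Downsample to 4096 Hz, 80 Hz high-pass (+240 Hz low-pass for the
    F0-band variant), trim one second from each trial edge."""
    if eeg.rate < 2 * SUBCORTICAL_RATE:
        raise ValueError("EEG rate must be at least 8192 Hz")
    k = int(round(trim * SUBCORTICAL_RATE))
    trials = []
    for t in eeg.trials:
        x = resample_to(t, eeg.rate, SUBCORTICAL_RATE, mode=mode, **AA_4096)
        x = fir_filter(x, SUBCORTICAL_RATE, HIGHPASS_80["cutoff"], "highpass",
                       transition=HIGHPASS_80["transition"], mode=mode)
        if f0_variant:
            x = fir_filter(x, SUBCORTICAL_RATE, LOWPASS_240["cutoff"], "lowpass",
                           transition=LOWPASS_240["transition"], mode=mode)
        if x.shape[-1] - 2 * k <= 0:
            raise ValueError("trial too short after trimming")
        trials.append(x[:, k:x.shape[-1] - k])
    return EEGRecording(trials, SUBCORTICAL_RATE, eeg.channel_labels, eeg.reference)


def cortical_chain(eeg: EEGRecording, mode: str = "compensated") -> EEGRecording:
    """Resample to 64 Hz, 0.5 Hz high-pass, then 1–9 Hz band-pass."""
    if eeg.rate < 128:
        raise ValueError("EEG rate must be at least 128 Hz")
    trials = []
    for t in eeg.trials:
        x = resample_to(t, eeg.rate, 64.0, aa_cutoff=30.0, aa_transition=7.5,
                        mode=mode)
        x = fir_filter(x, 64.0, 0.5, "highpass", transition=1.0, mode=mode)
        x = fir_filter(x, 64.0, 1.0, "highpass", order=106, mode=mode)
        x = fir_filter(x, 64.0, 9.0, "lowpass", order=94, mode=mode)
        trials.append(x)
    return EEGRecording(trials, 64.0, eeg.channel_labels, eeg.reference)


def linenoise_filter(eeg: EEGRecording, freqs=(50.0, 100.0, 150.0),
                     bandwidths=(1.0, 2.0, 3.0)) -> EEGRecording:
    """Remove narrow spectral bands (DFT filter) per trial.

    Frequency bins within ``f +/- bw/2`` are zeroed for each listed line
    frequency.
    """
    if len(freqs) != len(bandwidths):
        raise ValueError("freqs and bandwidths must have equal length")
    nyq = eeg.rate / 2.0
    for f, bw in zip(freqs, bandwidths):
        if f >= nyq:
            raise ValueError(f"line frequency {f} Hz at or above Nyquist")
        if f - bw / 2.0 <= 0:
            raise ValueError("band overlaps 0 Hz")
    trials = []
    for t in eeg.trials:
        n = t.shape[-1]
        spec = np.fft.rfft(t, axis=-1)
        fax = np.fft.rfftfreq(n, 1.0 / eeg.rate)
        for f, bw in zip(freqs, bandwidths):
            spec[:, np.abs(fax - f) <= bw / 2.0] = 0.0
        trials.append(np.fft.irfft(spec, n=n, axis=-1))
    return EEGRecording(trials, eeg.rate, eeg.channel_labels, eeg.reference)


def epoch_average_abr(eeg: EEGRecording, event_times, window_ms=(-5.0, 20.0),
                      reject_threshold: float = 20.0,
                      variance_weighting: bool = True,
                      presentation_delay_ms: float = 1.05,
                      channel: str | int = 0) -> ABRWaveform:
    """Epoch at click onsets, reject artifacts, variance-weight and average.

    Epochs containing any sample with ``|x| > reject_threshold`` (microvolt)
    are dropped; surviving epochs are divided by their variance before
    averaging. The presentation delay (trigger-to-eardrum) is subtracted
    from the lag axis so lag 0 is acoustic stimulation.
    """
    lo, hi = window_ms
    if not lo < hi:
        raise ValueError("window must be increasing")
    if not (lo <= 0.0 <= hi):
        raise ValueError("window must contain lag 0")
    data = eeg.trials[0]
    ch = eeg.channel_index(channel) if isinstance(channel, str) else channel
    x = data[ch]
    rate = eeg.rate
    i_lo = int(round(lo / 1000.0 * rate))
    i_hi = int(round(hi / 1000.0 * rate))
    length = i_hi - i_lo + 1
    epochs = []
    n_rejected = 0
    event_times = np.asarray(event_times, dtype=float)
    for t0 in event_times:
        c = int(round(t0 * rate))
        a, b = c + i_lo, c + i_lo + length
        if a < 0 or b > x.size:
            raise ValueError(f"event at {t0} s falls outside the recording")
        ep = x[a:b]
        if np.max(np.abs(ep)) > reject_threshold:
            n_rejected += 1
            continue
        epochs.append(ep)
    if not epochs:
        raise ValueError("all epochs rejected")
    epochs = np.asarray(epochs)
    if variance_weighting:
        v = epochs.var(axis=1, keepdims=True)
        v[v == 0] = 1.0
        epochs = epochs / v
    avg = epochs.mean(axis=0)
    lags_ms = (np.arange(i_lo, i_hi + 1) / rate) * 1000.0 - presentation_delay_ms
    return ABRWaveform(lags_ms=lags_ms, amplitude=avg,
                       n_kept=len(epochs), n_rejected=n_rejected)
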
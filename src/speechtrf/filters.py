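"""Shared FIR filter engine for audio and EEG conditioning.

Both signal families are conditioned with the same windowed-sinc
(Hamming) FIR designs so that stimulus features and neural responses see
identical group delays. The filter order follows the classic Hamming-window
design rule ``order = ceil(3.3 * fs / transition_width)`` (rounded up to an
even order so the group delay is an integer number of samples).

Application modes:

``compensated``
    one-pass filtering with the linear-phase group delay removed afterwards
    (zero effective delay, mild acausal leakage limited to half the filter
    length);
``causal``
    plain one-pass filtering, output delayed by the group delay — used when
    late response components must not leak backwards in time;
``twopass``
    forward-backward filtering (zero phase, squared magnitude response).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "fir_order",
    "design_fir",
    "apply_fir",
    "fir_filter",
    "decimate_by",
    "resample_to",
]

_MODES = ("compensated", "causal", "twopass")


def fir_order(rate: float, transition: float) -> int:
    """Even Hamming-window FIR order for a given transition width (Hz)."""
    if transition <= 0:
        raise ValueError("transition width must be positive")
    n = int(np.ceil(3.3 * rate / transition))
    return n + (n % 2)


def design_fir(rate: float, cutoff, btype: str = "lowpass",
               transition: float | None = None, order: int | None = None) -> np.ndarray:
    """Design Hamming windowed-sinc FIR taps.

    ``cutoff`` is a scalar (low/highpass) or pair (bandpass) in Hz. Exactly
    one of ``transition`` / ``order`` sets the length; ``order`` wins if both
    are given (must be even).
    """
    if order is None:
        if transition is None:
            raise ValueError("give either transition or order")
        order = fir_order(rate, transition)
    if order % 2:
        raise ValueError("order must be even for integer group delay")
    cutoff = np.atleast_1d(np.asarray(cutoff, dtype=float))
    nyq = rate / 2.0
    if np.any(cutoff <= 0) or np.any(cutoff >= nyq):
        raise ValueError(f"cutoff {cutoff} outside (0, {nyq}) Hz")
    if btype == "lowpass":
        return signal.firwin(order + 1, cutoff, window="hamming", fs=rate)
    if btype == "highpass":
        # spectral inversion of the complementary low-pass: exact DC null
        taps = -signal.firwin(order + 1, cutoff, window="hamming", fs=rate)
        taps[order // 2] += 1.0
        return taps
    if btype == "bandpass":
        lo, hi = cutoff
        return (signal.firwin(order + 1, hi, window="hamming", fs=rate)
                - signal.firwin(order + 1, lo, window="hamming", fs=rate))
    raise ValueError("btype must be lowpass, highpass or bandpass")


def apply_fir(x: np.ndarray, taps: np.ndarray, mode: str = "compensated") -> np.ndarray:
    """Apply FIR taps along the last axis, preserving length."""
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    if mode == "twopass":
        if n <= 3 * len(taps):
            # filtfilt needs padding room; fall back to reflective padding
            return signal.filtfilt(taps, [1.0], x, padlen=min(n - 2, len(taps)))
        return signal.filtfilt(taps, [1.0], x)
    t = np.asarray(taps, dtype=np.float64).reshape((1,) * (x.ndim - 1) + (-1,))
    full = signal.fftconvolve(x, t, mode="full", axes=-1)
    if mode == "causal":
        return full[..., :n]
    delay = (len(taps) - 1) // 2
    return full[..., delay:delay + n]


def fir_filter(x: np.ndarray, rate: float, cutoff, btype: str = "lowpass",
               transition: float | None = None, order: int | None = None,
               mode: str = "compensated") -> np.ndarray:
    """Design and apply in one call."""
    taps = design_fir(rate, cutoff, btype=btype, transition=transition, order=order)
    return apply_fir(x, taps, mode=mode)


def decimate_by(x: np.ndarray, rate: float, factor: int, aa_cutoff: float,
                aa_transition: float, mode: str = "compensated") -> np.ndarray:
    """Anti-alias filter then keep every ``factor``-th sample (last axis)."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    y = fir_filter(x, rate, aa_cutoff, "lowpass", transition=aa_transition, mode=mode)
    return y[..., ::int(factor)]


def resample_to(x: np.ndarray, rate_in: float, rate_out: float,
                aa_cutoff: float | None = None, aa_transition: float | None = None,
                mode: str = "compensated") -> np.ndarray:
    """Resample along the last axis.

    Integer downsampling uses the explicit anti-alias FIR + sample picking;
    other ratios go through polyphase resampling (after the explicit
    anti-alias filter if one is specified).
    """
    if rate_in == rate_out:
        return np.asarray(x, dtype=np.float64)
    ratio = rate_in / rate_out
    if aa_cutoff is not None and aa_transition is not None and rate_out < rate_in:
        if abs(ratio - round(ratio)) < 1e-9:
            return decimate_by(x, rate_in, int(round(ratio)), aa_cutoff, aa_transition, mode)
        x = fir_filter(x, rate_in, aa_cutoff, "lowpass", transition=aa_transition, mode=mode)
    from fractions import Fraction
    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
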
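"""Core in-memory containers shared across the package.

These are deliberately thin dataclasses around numpy arrays: a mono audio
waveform, a per-trial stimulus feature series, trial-segmented multichannel
EEG, a ground-truth response kernel used in simulations, and the two model
result containers (real-valued TRF weights and the complex cross-correlation
response).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AudioSignal",
    "FeatureSeries",
    "EEGRecording",
    "GroundTruthKernel",
    "ComplexResponse",
    "TRFModel",
    "ABRWaveform",
    "PeakEstimate",
    "ModelComparison",
    "SyntheticSession",
]


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class AudioSignal:
    """Mono pressure waveform (arbitrary units) with its sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        self.samples = _as_1d_float(self.samples, "samples")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


#: recognised stimulus feature labels
FEATURE_LABELS = ("broadband_rectified", "f0_band", "envelope", "relative_pitch")


@dataclass
class FeatureSeries:
    """Single-trial stimulus feature time series aligned to the EEG rate."""

    samples: np.ndarray
    rate: float
    label: str = "feature"
    zscored: bool = False

    def __post_init__(self):
        self.samples = _as_1d_float(self.samples, "samples")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class EEGRecording:
    """Trial-segmented EEG: a list of (channels x samples) arrays in microvolt.

    All trials must share the channel count; sampling rate applies to all.
    """

    trials: list
    rate: float
    channel_labels: list
    reference: str = "raw"

    def __post_init__(self):
        self.trials = [np.atleast_2d(np.asarray(t, dtype=np.float64)) for t in self.trials]
        if not self.trials:
            raise ValueError("EEGRecording needs at least one trial")
        n_ch = self.trials[0].shape[0]
        for i, t in enumerate(self.trials):
            if t.shape[0] != n_ch:
                raise ValueError(f"trial {i} has {t.shape[0]} channels, expected {n_ch}")
            if not np.all(np.isfinite(t)):
                raise ValueError(f"trial {i} contains non-finite values")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels length must match channel count")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in {self.channel_labels}") from None


@dataclass
class GroundTruthKernel:
    """A known impulse response h(lag) used to synthesize EEG from features.

    ``lags`` is a strictly increasing, uniformly spaced axis in seconds;
    ``amplitude`` holds the response value per lag (arbitrary units).
    """

    lags: np.ndarray
    amplitude: np.ndarray
    label: str = "kernel"

    def __post_init__(self):
        self.lags = _as_1d_float(self.lags, "lags")
        self.amplitude = _as_1d_float(self.amplitude, "amplitude")
        if self.lags.size != self.amplitude.size:
            raise ValueError("lags and amplitude must have equal length")
        if self.lags.size < 2:
            raise ValueError("kernel needs at least two lag samples")
        d = np.diff(self.lags)
        if np.any(d <= 0):
            raise ValueError("lag axis must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
            raise ValueError("lag axis must be uniformly spaced")

    @property
    def rate(self) -> float:
        return 1.0 / (self.lags[1] - self.lags[0])

    @property
    def duration(self) -> float:
        return self.lags[-1] - self.lags[0]

    @property
    def peak_latency(self) -> float:
        """Latency (s) of the kernel maximum."""
        return float(self.lags[int(np.argmax(self.amplitude))])


@dataclass
class ComplexResponse:
    """Complex cross-correlation function over lags.

    The real part is the lagged correlation of the feature with the EEG, the
    imaginary part the same for the feature's quadrature (Hilbert transform);
    the magnitude is interpreted as the response envelope over lags.
    """

    lag_axis: np.ndarray
    real: np.ndarray
    imag: np.ndarray

    def __post_init__(self):
        self.lag_axis = _as_1d_float(self.lag_axis, "lag_axis")
        self.real = _as_1d_float(self.real, "real")
        self.imag = _as_1d_float(self.imag, "imag")
        if not (self.lag_axis.size == self.real.size == self.imag.size):
            raise ValueError("lag_axis, real and imag must share length")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.real, self.imag)


@dataclass
class TRFModel:
    """Estimated temporal response function.

    ``weights`` has shape (n_channels, n_features, n_lags); ``lam`` is the
    ridge parameter used (0 = ordinary least squares); ``cv_accuracy`` holds
    per-channel mean Pearson r on held-out data when cross-validation was run.
    """

    weights: np.ndarray
    lam: float
    lag_axis: np.ndarray
    rate: float
    feature_labels: list = field(default_factory=list)
    cv_accuracy: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise ValueError("weights must be (channels, features, lags)")
        self.lag_axis = _as_1d_float(self.lag_axis, "lag_axis")
        if self.weights.shape[2] != self.lag_axis.size:
            raise ValueError("weights last axis must match lag_axis")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.feature_labels and len(self.feature_labels) != self.weights.shape[1]:
            raise ValueError("feature_labels must match weight feature axis")

    def channel(self, index: int, feature: int = 0) -> np.ndarray:
        return self.weights[index, feature]


@dataclass
class ABRWaveform:
    """Averaged click-evoked response after artifact rejection.

    ``lags_ms`` is relative to acoustic stimulation (presentation delay
    already subtracted); amplitude is in arbitrary units after per-epoch
    variance weighting.
    """

    lags_ms: np.ndarray
    amplitude: np.ndarray
    n_kept: int
    n_rejected: int

    def __post_init__(self):
        self.lags_ms = _as_1d_float(self.lags_ms, "lags_ms")
        self.amplitude = _as_1d_float(self.amplitude, "amplitude")
        if self.lags_ms.size != self.amplitude.size:
            raise ValueError("lags_ms and amplitude must share length")


@dataclass
class PeakEstimate:
    """Latency and amplitude of a response maximum inside a pre-defined window."""

    latency_ms: float
    amplitude: float
    window_ms: tuple
    channel_set: str = ""

    def __post_init__(self):
        lo, hi = self.window_ms
        if not (lo <= self.latency_ms <= hi):
            raise ValueError("latency must lie inside the window")


@dataclass
class ModelComparison:
    """Per-subject accuracies of two individual models and their combination."""

    accuracy_a: np.ndarray
    accuracy_b: np.ndarray
    accuracy_combined: np.ndarray
    improvement: np.ndarray  # combined - best individual, per subject
    p_values: dict  # contrast name -> raw p
    p_values_fdr: dict  # contrast name -> B-Y adjusted p
    n_permutations: int
    seed: int


@dataclass
class SyntheticSession:
    """A fully synthetic recording session.

    ``audio`` holds one stimulus per trial; ``eeg`` the matching trial-
    segmented EEG; ``features`` the ground-truth feature series actually
    convolved (label -> list over trials); ``kernels`` the ground-truth
    response kernels (one per driving feature). ``seed`` fully determines
    all content.
    """

    audio: list
    eeg: EEGRecording
    features: dict
    kernels: list
    snr_db: float
    seed: int

    def __post_init__(self):
        if len(self.audio) != self.eeg.n_trials:
            raise ValueError("audio and EEG trial counts differ")
        rates = {a.rate for a in self.audio}
        if len(rates) > 1:
            raise ValueError("all audio trials must share the sampling rate")

    @property
    def trials(self):
        """(AudioSignal, single-trial EEG array) pairs."""
        return list(zip(self.audio, self.eeg.trials))
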
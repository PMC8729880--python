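"""File formats: WAV audio, TSV tables, and HDF5 session containers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .containers import (
    AudioSignal,
    EEGRecording,
    FeatureSeries,
    GroundTruthKernel,
    SyntheticSession,
    TRFModel,
)

__all__ = [
    "read_wav",
    "write_wav",
    "write_events_tsv",
    "read_events_tsv",
    "save_session",
    "load_session",
    "trf_to_frame",
    "write_trf_tsv",
    "write_manifest",
    "load_config",
    "export_pipeline_bundle",
]


def read_wav(path) -> AudioSignal:
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioSignal(data.astype(np.float64), float(rate))


def write_wav(path, audio: AudioSignal):
    wavfile.write(path, int(round(audio.rate)), audio.samples.astype(np.float32))


def write_events_tsv(path, onsets_s, polarity=None):
    """Two-column event table: onset_s, polarity (+1/-1, alternating default)."""
    onsets_s = np.asarray(onsets_s, dtype=float)
    if polarity is None:
        polarity = np.where(np.arange(onsets_s.size) % 2 == 0, 1, -1)
    pd.DataFrame({"onset_s": onsets_s, "polarity": polarity}).to_csv(
        path, sep="\t", index=False)


def read_events_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return df["onset_s"].to_numpy(), df["polarity"].to_numpy()


def save_session(path, session: SyntheticSession):
    """Hierarchical container: trials/<i>/{audio,eeg}, features, kernels."""
    with h5py.File(path, "w") as f:
        f.attrs["snr_db"] = session.snr_db
        f.attrs["seed"] = session.seed
        f.attrs["eeg_rate"] = session.eeg.rate
        f.attrs["audio_rate"] = session.audio[0].rate
        f.attrs["channel_labels"] = [str(l) for l in session.eeg.channel_labels]
        f.attrs["reference"] = session.eeg.reference
        tg = f.create_group("trials")
        for i, (aud, eeg) in enumerate(session.trials):
            g = tg.create_group(str(i))
            g.create_dataset("audio", data=aud.samples)
            g.create_dataset("eeg", data=eeg)
        fg = f.create_group("features")
        for label, series_list in session.features.items():
            lg = fg.create_group(label)
            lg.attrs["rate"] = series_list[0].rate
            lg.attrs["zscored"] = series_list[0].zscored
            for i, s in enumerate(series_list):
                lg.create_dataset(str(i), data=s.samples)
        kg = f.create_group("kernels")
        for k in session.kernels:
            g = kg.create_group(k.label)
            g.create_dataset("lags", data=k.lags)
            g.create_dataset("amplitude", data=k.amplitude)


def load_session(path) -> SyntheticSession:
    with h5py.File(path, "r") as f:
        n = len(f["trials"])
        audio_rate = float(f.attrs["audio_rate"])
        eeg_rate = float(f.attrs["eeg_rate"])
        labels = [str(l) for l in f.attrs["channel_labels"]]
        audio, eeg_trials = [], []
        for i in range(n):
            g = f["trials"][str(i)]
            audio.append(AudioSignal(g["audio"][()], audio_rate))
            eeg_trials.append(g["eeg"][()])
        features = {}
        for label in f["features"]:
            lg = f["features"][label]
            rate = float(lg.attrs["rate"])
            zs = bool(lg.attrs["zscored"])
            features[label] = [
                FeatureSeries(lg[str(i)][()], rate, label=label, zscored=zs)
                for i in range(n)]
        kernels = []
        for label in f["kernels"]:
            g = f["kernels"][label]
            kernels.append(GroundTruthKernel(g["lags"][()], g["amplitude"][()],
                                             label=label))
        eeg = EEGRecording(eeg_trials, eeg_rate, labels,
                           reference=str(f.attrs["reference"]))
        return SyntheticSession(audio=audio, eeg=eeg, features=features,
                                kernels=kernels, snr_db=float(f.attrs["snr_db"]),
                                seed=int(f.attrs["seed"]))


def trf_to_frame(trf: TRFModel, channel_labels=None) -> pd.DataFrame:
    """Long-format weight table: lag_ms, channel, feature, weight."""
    n_ch, n_feat, n_lag = trf.weights.shape
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_ch)]
    feats = trf.feature_labels or [f"feature{i}" for i in range(n_feat)]
    rows = []
    for ci, cl in enumerate(channel_labels):
        for fi, fl in enumerate(feats):
            for li in range(n_lag):
                rows.append((trf.lag_axis[li] * 1000.0, cl, fl,
                             trf.weights[ci, fi, li]))
    return pd.DataFrame(rows, columns=["lag_ms", "channel", "feature", "weight"])


def write_trf_tsv(path, trf: TRFModel, channel_labels=None):
    trf_to_frame(trf, channel_labels).to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def write_manifest(out_dir, config: dict, extra: dict | None = None):
    """Record the configuration, its hash, and package versions of a run."""
    from . import __version__
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    canon = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "versions": {"speechtrf": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    if extra:
        manifest.update(extra)
    with open(out / "manifest.yaml", "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=False, default_flow_style=False)
    return manifest


def export_pipeline_bundle(bundle: dict, out_dir):
    """Write the pipeline's tables and TRF exports as TSV plus a manifest."""
    from dataclasses import asdict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["subjects"].to_csv(out / "subjects.tsv", sep="\t", index=False)
    bundle["comparison_table"].to_csv(out / "model_comparison.tsv", sep="\t",
                                      index=False)
    bundle["correlations"].to_csv(out / "correlations.tsv", sep="\t",
                                  index=False)
    for si, trf in enumerate(bundle["subcortical_trfs"]):
        write_trf_tsv(out / f"subcortical_trf_subject{si:02d}.tsv", trf, ["Cz"])
    cfg = asdict(bundle["config"])
    write_manifest(out, cfg, {"kernel_truth": bundle["kernel_truth"]})
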
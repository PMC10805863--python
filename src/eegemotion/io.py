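"""Readers, writers, and the end-to-end pipeline driver.

Array data travels in HDF5 containers, tabular metadata in CSV, configs and
montages in JSON -- no pickles.  ``read_eeg`` accepts DEAP-style MATLAB
files (``data``: trials x channels x samples, ``labels``: trials x ratings),
EDF recordings (via mne), and the package's own synthetic container.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import DEFAULT_BANDS, BandDefinition, Montage, windows_to_tensors
from .preprocessing import (
    EmotionLabel,
    RawEEGRecord,
    Trial,
    preprocess_record,
)
from .synthetic import SyntheticDataset, SyntheticSpec, generate_eeg, generate_visual_features
from .training import (
    DistillationConfig,
    binary_metrics,
    evaluate_eeg,
    report_band_attention,
    train_eeg_distilled,
)
from .eeg_network import EEGNet, EEGNetConfig

__all__ = [
    "PipelineConfig",
    "PROFILES",
    "write_synthetic_dataset",
    "read_eeg",
    "write_features",
    "read_features",
    "write_metrics",
    "write_checkpoint",
    "read_checkpoint",
    "run_pipeline",
]

# dataset profile defaults: (sampling rate, window seconds, baseline s, middle s)
PROFILES = {
    "deap-like": {"sampling_rate": 128.0, "window_seconds": 2.0,
                  "baseline_seconds": 3.0, "middle_seconds": None},
    "mahnob-like": {"sampling_rate": 256.0, "window_seconds": 0.5,
                    "baseline_seconds": 3.0, "middle_seconds": 30.0},
    "synthetic": {"sampling_rate": 128.0, "window_seconds": 2.0,
                  "baseline_seconds": 2.0, "middle_seconds": None},
}


@dataclass
class PipelineConfig:
    profile: str = "synthetic"
    spec: SyntheticSpec = field(default_factory=SyntheticSpec)
    window_seconds: float | None = None  # None -> profile default
    t_slices: int = 4
    teacher_snr: float = 6.0
    net: EEGNetConfig = field(default_factory=lambda: EEGNetConfig().small())
    train: DistillationConfig = field(
        default_factory=lambda: DistillationConfig(rho=0.8, learning_rate_eeg=3e-3,
                                                   epochs=10, batch_size=32)
    )
    out_dir: str = "pipeline_out"

    def resolved_window(self) -> float:
        if self.window_seconds is not None:
            return self.window_seconds
        return PROFILES[self.profile]["window_seconds"]


def config_hash(obj) -> str:
    payload = json.dumps(_jsonable(obj), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


# ---------------------------------------------------------------------------
# synthetic container
# ---------------------------------------------------------------------------

def write_synthetic_dataset(dataset: SyntheticDataset, out_dir) -> Path:
    """One HDF5 per subject + trial-rating CSV + JSON copy of the spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset.records:
        with h5py.File(out / f"{rec.subject_id}.h5", "w") as fh:
            fh.attrs["subject_id"] = rec.subject_id
            fh.attrs["sampling_rate"] = rec.sampling_rate
            fh.attrs["channel_names"] = json.dumps(rec.channel_names)
            for i, t in enumerate(rec.trials):
                g = fh.create_group(f"trial{i:03d}")
                g.create_dataset("signal", data=t.signal)
                g.create_dataset("baseline", data=t.baseline)
                g.attrs["ratings"] = json.dumps(t.ratings)
                for dim, r in t.ratings.items():
                    rows.append({"subject": rec.subject_id, "trial": i, "dimension": dim,
                                 "rating": r, "label": EmotionLabel.from_rating(dim, r).klass})
    pd.DataFrame(rows).to_csv(out / "ratings.csv", index=False)
    with open(out / "spec.json", "w") as fh:
        json.dump(_jsonable(dataset.truth), fh, indent=2)
    return out


def _read_synthetic_h5(path) -> RawEEGRecord:
    with h5py.File(path, "r") as fh:
        names = json.loads(fh.attrs["channel_names"])
        trials = []
        for key in sorted(k for k in fh if k.startswith("trial")):
            g = fh[key]
            trials.append(Trial(signal=g["signal"][...], baseline=g["baseline"][...],
                                ratings=json.loads(g.attrs["ratings"])))
        return RawEEGRecord(subject_id=str(fh.attrs["subject_id"]), trials=trials,
                            sampling_rate=float(fh.attrs["sampling_rate"]),
                            channel_names=names)


def _read_deap_mat(path, profile: dict, montage: Montage,
                   dimensions=("valence", "arousal")) -> RawEEGRecord:
    from scipy.io import loadmat

    mat = loadmat(path)
    data = mat["data"]  # trials x channels x samples
    ratings = mat["labels"]  # trials x >=2 (valence, arousal, ...)
    names = montage.channel_names
    n_ch = len(names)
    if data.shape[1] < n_ch:
        raise ValueError(f"file has {data.shape[1]} channels; montage expects {n_ch}")
    fs = profile["sampling_rate"]
    n_base = int(profile["baseline_seconds"] * fs)
    trials = []
    for i in range(data.shape[0]):
        sig = np.asarray(data[i, :n_ch, :], dtype=float)
        rate = {dim: int(np.clip(round(float(ratings[i, j])), 1, 9))
                for j, dim in enumerate(dimensions)}
        trials.append(Trial(signal=sig[:, n_base:], baseline=sig[:, :n_base], ratings=rate))
    return RawEEGRecord(subject_id=Path(path).stem, trials=trials,
                        sampling_rate=fs, channel_names=names)


def _read_edf(path, profile: dict, montage: Montage) -> RawEEGRecord:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = [n for n in montage.channel_names if n in raw.ch_names]
    missing = [n for n in montage.channel_names if n not in raw.ch_names]
    if missing:
        raise ValueError(f"EDF is missing montage channels: {missing}")
    data = raw.get_data(picks=names)
    fs = float(raw.info["sfreq"])
    n_base = int(profile["baseline_seconds"] * fs)
    trial = Trial(signal=data[:, n_base:], baseline=data[:, :n_base],
                  ratings={"valence": 5, "arousal": 5})
    return RawEEGRecord(subject_id=Path(path).stem, trials=[trial],
                        sampling_rate=fs, channel_names=names)


def read_eeg(path, profile: str = "deap-like", montage: Montage | None = None) -> RawEEGRecord:
    """Load one subject's record from .mat, .edf, or the synthetic .h5 container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    montage = montage or Montage.default_32()
    prof = PROFILES[profile]
    if path.suffix == ".h5":
        return _read_synthetic_h5(path)
    if path.suffix == ".mat":
        return _read_deap_mat(path, prof, montage)
    if path.suffix in (".edf", ".bdf"):
        return _read_edf(path, prof, montage)
    raise ValueError(f"unsupported EEG format: {path.suffix}")


# ---------------------------------------------------------------------------
# feature / metric / checkpoint containers
# ---------------------------------------------------------------------------

def write_features(path, features: np.ndarray, labels: np.ndarray, *,
                   montage: Montage, window_seconds: float,
                   bands=DEFAULT_BANDS) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("features", data=features)
        fh.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
        fh.attrs["bands"] = json.dumps([[b.name, b.low, b.high] for b in bands])
        fh.attrs["montage_hash"] = montage.hash()
        fh.attrs["window_seconds"] = window_seconds


def read_features(path):
    with h5py.File(path, "r") as fh:
        feats = fh["features"][...]
        labels = fh["labels"][...]
        meta = {
            "bands": [BandDefinition(n, lo, hi) for n, lo, hi in json.loads(fh.attrs["bands"])],
            "montage_hash": str(fh.attrs["montage_hash"]),
            "window_seconds": float(fh.attrs["window_seconds"]),
        }
    return feats, labels, meta


def write_metrics(path, metrics: dict, config=None, seed: int | None = None) -> None:
    payload = {"metrics": _jsonable(metrics)}
    if config is not None:
        payload["config"] = _jsonable(config)
        payload["config_hash"] = config_hash(config)
    if seed is not None:
        payload["seed"] = int(seed)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def write_checkpoint(path, model, config=None) -> None:
    state = model.state_dict()
    arrays = {k.replace(".", "/"): v for k, v in state.items()}
    meta = json.dumps({"config": _jsonable(config)}) if config is not None else "{}"
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def read_checkpoint(path, model) -> None:
    with np.load(path) as data:
        state = {k.replace("/", "."): data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """synth -> preprocess -> features -> teacher -> distilled training -> report.

    Features are cached in the output directory keyed by a config hash, so a
    re-run with the same configuration reuses (and reproduces) them.
    """
    from sklearn.model_selection import train_test_split

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = Montage.default_32()
    spec = config.spec
    window_seconds = config.resolved_window()

    cache_key = config_hash({"spec": _jsonable(spec), "window": window_seconds,
                             "t": config.t_slices})
    feature_file = out / f"features_{cache_key}.h5"
    dataset = generate_eeg(spec)
    write_synthetic_dataset(dataset, out / "raw")
    if not feature_file.exists():
        windows = []
        for rec in dataset.records:
            windows.extend(preprocess_record(rec, spec.dimension, window_seconds))
        names = dataset.records[0].channel_names
        feats, labels = windows_to_tensors(windows, config.t_slices, names, montage)
        write_features(feature_file, feats, labels, montage=montage,
                       window_seconds=window_seconds)
    else:
        feats, labels, _ = read_features(feature_file)

    teacher = np.stack(generate_visual_features(
        labels, config.t_slices, config.net.lstm_hidden,
        snr=config.teacher_snr, seed=spec.seed,
    ))
    idx_tr, idx_te = train_test_split(np.arange(len(labels)), test_size=0.25,
                                      stratify=labels, random_state=config.train.seed)
    model, history = train_eeg_distilled(
        feats[idx_tr], labels[idx_tr], teacher[idx_tr], config.train, config.net
    )
    pred = model(feats[idx_te]).probs.data.argmax(axis=1)
    metrics = binary_metrics(labels[idx_te], pred)
    band_report = (report_band_attention(model, feats)
                   if config.net.band_attention else None)
    write_metrics(out / "metrics.json", {"test": metrics, "band_attention": band_report},
                  config=config, seed=config.train.seed)
    history.to_csv(out / "training_log.csv", index=False)
    write_checkpoint(out / "eeg_model.npz", model, config=config.net)
    if band_report is not None:
        pd.DataFrame([{"band": b, "mean_weight": w} for b, w in band_report.items()]
                     ).to_csv(out / "band_attention.csv", index=False)
    return {"metrics": metrics, "band_attention": band_report,
            "feature_file": str(feature_file), "n_windows": int(len(labels))}
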
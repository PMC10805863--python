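"""EEG preprocessing: baseline removal, windowing, and rating binarisation.

The pipeline mirrors the common preparation of trial-based affective EEG
datasets (DEAP-like at 128 Hz, MAHNOB-like at 256 Hz): each trial carries a
pre-stimulus baseline segment and a stimulus ("experimental") segment plus
1-9 self-assessment ratings on the valence and arousal dimensions.  The
baseline is summarised by the per-channel mean over non-overlapping windows
and subtracted from every experimental window; the experimental signal is
then cut into non-overlapping windows that become the classification
samples.  Ratings are binarised at 5 (rating > 5 -> "high").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmotionLabel",
    "Trial",
    "RawEEGRecord",
    "EEGWindow",
    "binarize_rating",
    "remove_baseline",
    "segment_windows",
    "select_middle_segment",
    "preprocess_record",
]

RATING_THRESHOLD = 5  # rating > 5 -> high class


def binarize_rating(rating: int) -> str:
    """Binarise a 1-9 self-assessment rating; exactly 5 maps to ``low``."""
    r = int(rating)
    if not 1 <= r <= 9:
        raise ValueError(f"rating must be in [1, 9], got {rating}")
    return "high" if r > RATING_THRESHOLD else "low"


@dataclass(frozen=True)
class EmotionLabel:
    dimension: str  # "valence" | "arousal"
    klass: str  # "low" | "high"
    raw_rating: int

    def __post_init__(self):
        if self.klass != binarize_rating(self.raw_rating):
            raise ValueError(f"class {self.klass!r} inconsistent with rating {self.raw_rating}")

    @classmethod
    def from_rating(cls, dimension: str, rating: int) -> "EmotionLabel":
        return cls(dimension, binarize_rating(rating), int(rating))

    @property
    def index(self) -> int:
        """0 for low, 1 for high (the positive class)."""
        return 1 if self.klass == "high" else 0


@dataclass
class Trial:
    signal: np.ndarray  # channels x samples, stimulus period
    baseline: np.ndarray  # channels x samples, pre-stimulus period
    ratings: dict[str, int]  # dimension -> 1-9


@dataclass
class RawEEGRecord:
    subject_id: str
    trials: list[Trial]
    sampling_rate: float
    channel_names: list[str]

    def __post_init__(self):
        n_ch = len(self.channel_names)
        for i, t in enumerate(self.trials):
            if t.signal.shape[0] != n_ch or t.baseline.shape[0] != n_ch:
                raise ValueError(f"trial {i}: channel count mismatch with channel_names")
            for dim, r in t.ratings.items():
                if not 1 <= int(r) <= 9:
                    raise ValueError(f"trial {i}: rating {r} for {dim} outside [1, 9]")


@dataclass
class EEGWindow:
    data: np.ndarray  # channels x samples
    window_seconds: float
    sampling_rate: float
    trial_id: int = 0
    subject_id: str = ""
    label: EmotionLabel | None = None


def _window_samples(window_seconds: float, sampling_rate: float) -> int:
    n = window_seconds * sampling_rate
    n_int = int(round(n))
    if n_int <= 0 or abs(n - n_int) > 1e-9:
        raise ValueError(
            f"window_seconds x sampling_rate must be a positive integer, got {n}"
        )
    return n_int


def remove_baseline(
    trial_signal: np.ndarray,
    baseline_signal: np.ndarray,
    window_seconds: float,
    sampling_rate: float,
) -> np.ndarray:
    """Subtract the mean baseline window from every experimental window.

    The baseline is cut into non-overlapping windows of ``window_seconds``;
    their per-channel elementwise mean is the baseline template, which is
    subtracted from each consecutive window of the experimental signal.  A
    trailing partial window has the leading part of the template subtracted,
    so the output has the same length as the input.
    """
    if trial_signal.shape[0] != baseline_signal.shape[0]:
        raise ValueError("trial and baseline must share the channel count")
    n = _window_samples(window_seconds, sampling_rate)
    n_base = baseline_signal.shape[1] // n
    if n_base < 1:
        raise ValueError(
            f"baseline ({baseline_signal.shape[1]} samples) shorter than one "
            f"window ({n} samples)"
        )
    template = (
        baseline_signal[:, : n_base * n]
        .reshape(baseline_signal.shape[0], n_base, n)
        .mean(axis=1)
    )
    out = np.array(trial_signal, dtype=float, copy=True)
    total = out.shape[1]
    for start in range(0, total, n):
        stop = min(start + n, total)
        out[:, start:stop] -= template[:, : stop - start]
    return out


def segment_windows(
    signal: np.ndarray,
    window_seconds: float,
    sampling_rate: float,
    *,
    trial_id: int = 0,
    subject_id: str = "",
    label: EmotionLabel | None = None,
) -> list[EEGWindow]:
    """Cut a channels x samples signal into non-overlapping windows.

    The trailing remainder that does not fill a whole window is discarded.
    A signal shorter than one window yields an empty list.
    """
    n = _window_samples(window_seconds, sampling_rate)
    k = signal.shape[1] // n
    return [
        EEGWindow(
            data=signal[:, i * n : (i + 1) * n],
            window_seconds=window_seconds,
            sampling_rate=sampling_rate,
            trial_id=trial_id,
            subject_id=subject_id,
            label=label,
        )
        for i in range(k)
    ]


def select_middle_segment(
    signal: np.ndarray, keep_seconds: float, sampling_rate: float
) -> np.ndarray:
    """Return the centred ``keep_seconds`` span of the signal.

    When the number of trimmed samples is odd the extra sample is trimmed
    from the head side.
    """
    keep = _window_samples(keep_seconds, sampling_rate)
    total = signal.shape[1]
    if total < keep:
        raise ValueError(f"signal ({total} samples) shorter than keep span ({keep})")
    rem = total - keep
    head = rem - rem // 2
    return signal[:, head : head + keep]


def preprocess_record(
    record: RawEEGRecord,
    dimension: str,
    window_seconds: float,
    *,
    middle_seconds: float | None = None,
    baseline_removal: bool = True,
) -> list[EEGWindow]:
    """Full per-record preparation: (middle crop) -> baseline removal -> windows."""
    windows: list[EEGWindow] = []
    for i, trial in enumerate(record.trials):
        sig = trial.signal
        if middle_seconds is not None:
            sig = select_middle_segment(sig, middle_seconds, record.sampling_rate)
        if baseline_removal:
            sig = remove_baseline(sig, trial.baseline, window_seconds, record.sampling_rate)
        label = EmotionLabel.from_rating(dimension, trial.ratings[dimension])
        windows.extend(
            segment_windows(
                sig,
                window_seconds,
                record.sampling_rate,
                trial_id=i,
                subject_id=record.subject_id,
                label=label,
            )
        )
    return windows
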
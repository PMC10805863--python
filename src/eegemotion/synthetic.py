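"""Synthetic multimodal emotion data with known, controllable structure.

The EEG generator emulates trial-based affective recordings: every channel
is a sum of four narrowband oscillators (one per classical band, seeded
random frequency and phase) on top of 1/f ("pink") background noise, with a
pre-stimulus baseline segment drawn from the same background process.  The
class signal is injected as a variance scaling of the informative band's
oscillator on a chosen subset of electrodes, so an independent spectral
estimate can recover the injected band-power ratio and a trained band
attention has a known band to find.  Ratings are integers 1-9 consistent
with the binary class (low: 1-4, high: 6-9) and classes are balanced within
each subject to within one trial.

Visual "teacher" signals come in two forms: feature sequences (T x F, class
-separated means, noise of unit scale) and small 48x48x3 frame clips with a
class-dependent blob drift speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocessing import EmotionLabel, RawEEGRecord, Trial

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "VisualClip",
    "generate_eeg",
    "generate_visual_features",
    "generate_frame_clips",
    "BAND_RANGES",
]

BAND_RANGES = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (31.0, 50.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    n_subjects: int = 2
    n_trials_per_subject: int = 20
    trial_duration: float = 8.0  # seconds of stimulus signal
    baseline_duration: float = 2.0  # seconds of pre-stimulus signal
    sampling_rate: float = 128.0
    n_channels: int = 32
    informative_band: str = "gamma"
    informative_channels: tuple[int, ...] = (0, 2, 4, 6, 16, 18, 20, 24)
    effect_size: float = 3.0  # class-1 / class-0 band-power ratio
    noise_exponent: float = 1.0  # 1/f^alpha background slope
    oscillator_amplitude: float = 1.0
    noise_scale: float = 0.3
    dimension: str = "valence"
    # when on, the class-1 band-power boost scales with the trial's rating
    # intensity (rating 6 -> 1/4 of the full effect, 9 -> full), emulating
    # graded emotional arousal; off by default so effect_size is the exact
    # class-wise power ratio
    intensity_coupling: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.trial_duration <= 0 or self.baseline_duration <= 0:
            raise ValueError("durations must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.informative_band not in BAND_RANGES:
            raise ValueError(f"unknown band {self.informative_band!r}")
        if len(self.informative_channels) == 0:
            raise ValueError("informative_channels must be non-empty")
        if any(not 0 <= c < self.n_channels for c in self.informative_channels):
            raise ValueError("informative channel index out of range")


@dataclass
class SyntheticDataset:
    records: list[RawEEGRecord]
    labels: list[EmotionLabel]  # one per trial, concatenated over subjects
    truth: SyntheticSpec
    visual_features: list[np.ndarray] | None = None

    @property
    def label_indices(self) -> np.ndarray:
        return np.array([lab.index for lab in self.labels])

    @property
    def subject_ids(self) -> np.ndarray:
        out = []
        for rec in self.records:
            out.extend([rec.subject_id] * len(rec.trials))
        return np.array(out)


@dataclass
class VisualClip:
    frames: np.ndarray  # T x 48 x 48 x 3, values in [0, 1]
    label: EmotionLabel
    drift_speed: float = 0.0


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sampling_rate: float, exponent: float, scale: float) -> np.ndarray:
    """1/f^alpha noise via spectral shaping, unit-free scale = output std."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = amp * (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    )
    x = np.fft.irfft(spectrum, n=n_samples, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return scale * x / std


def _background(rng: np.random.Generator, spec: SyntheticSpec, n_samples: int,
                band_freqs: np.ndarray, gains: np.ndarray) -> np.ndarray:
    """Oscillators (per channel, per band) + pink noise.

    band_freqs: (n_channels, 4) oscillator frequencies; gains: (n_channels, 4)
    amplitude multipliers (the class effect enters here).
    """
    t = np.arange(n_samples) / spec.sampling_rate
    phases = rng.uniform(0, 2 * np.pi, size=band_freqs.shape)
    osc = (
        gains[:, :, None]
        * np.sin(2 * np.pi * band_freqs[:, :, None] * t[None, None, :] + phases[:, :, None])
    ).sum(axis=1)
    noise = _pink_noise(rng, spec.n_channels, n_samples, spec.sampling_rate,
                        spec.noise_exponent, spec.noise_scale)
    return osc + noise


def _balanced_classes(rng: np.random.Generator, n_trials: int) -> np.ndarray:
    """0/1 class per trial, balanced to within one, in shuffled order."""
    half = n_trials // 2
    classes = np.array([0] * half + [1] * (n_trials - half))
    rng.shuffle(classes)
    return classes


def generate_eeg(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a dataset of per-subject EEG records per the spec.

    Class-1 trials have the informative band's oscillator power multiplied
    by ``effect_size`` on the informative channels; everything else (other
    bands, other channels, pink noise, baseline segments) is class
    independent.
    """
    rng = np.random.default_rng(spec.seed)
    n_stim = int(round(spec.trial_duration * spec.sampling_rate))
    n_base = int(round(spec.baseline_duration * spec.sampling_rate))
    band_names = list(BAND_RANGES)
    info_idx = band_names.index(spec.informative_band)
    records: list[RawEEGRecord] = []
    labels: list[EmotionLabel] = []
    for s in range(spec.n_subjects):
        classes = _balanced_classes(rng, spec.n_trials_per_subject)
        trials: list[Trial] = []
        for klass in classes:
            lo_hi = np.array([BAND_RANGES[b] for b in band_names])
            freqs = rng.uniform(lo_hi[:, 0], lo_hi[:, 1], size=(spec.n_channels, 4))
            gains = np.full((spec.n_channels, 4), spec.oscillator_amplitude)
            rating = int(rng.integers(6, 10)) if klass == 1 else int(rng.integers(1, 5))
            if klass == 1:
                power_ratio = spec.effect_size
                if spec.intensity_coupling:
                    intensity = (rating - 5) / 4.0  # 6 -> 0.25 ... 9 -> 1.0
                    power_ratio = 1.0 + (spec.effect_size - 1.0) * intensity
                gains[list(spec.informative_channels), info_idx] *= np.sqrt(power_ratio)
            stim = _background(rng, spec, n_stim, freqs, gains)
            base_gains = np.full((spec.n_channels, 4), spec.oscillator_amplitude)
            base = _background(rng, spec, n_base, freqs, base_gains)
            label = EmotionLabel.from_rating(spec.dimension, rating)
            labels.append(label)
            trials.append(Trial(signal=stim, baseline=base, ratings={spec.dimension: rating}))
        names = _default_channel_names(spec.n_channels)
        records.append(
            RawEEGRecord(
                subject_id=f"s{s:02d}",
                trials=trials,
                sampling_rate=spec.sampling_rate,
                channel_names=names,
            )
        )
    return SyntheticDataset(records=records, labels=labels, truth=spec)


def _default_channel_names(n_channels: int) -> list[str]:
    from .features import Montage

    base = Montage.default_32().channel_names
    if n_channels <= len(base):
        return base[:n_channels]
    return base + [f"X{i}" for i in range(n_channels - len(base))]


def generate_visual_features(
    labels: list[EmotionLabel] | np.ndarray,
    t_steps: int,
    n_features: int,
    snr: float,
    seed: int,
    noise_std: float = 1.0,
    intensities: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Label-correlated T x F feature sequences (the distillation teacher).

    Class-conditional means sit at +/- snr*noise_std/2 along a fixed random
    unit direction, so ``snr`` is the mean separation in noise-std units
    regardless of the absolute scale; snr = 0 makes the sequences label
    independent.  A small ``noise_std`` emulates the near-deterministic
    features a trained visual network emits for clips of one class.

    ``intensities`` (optional, one signed value in [-1, 1] per label) grades
    the mean by the trial's emotional intensity: the i-th mean becomes
    intensities[i] * snr * noise_std / 2 along the class direction, the way
    facial expressiveness scales with rating distance from neutral.  Without
    it each class sits at full +/- intensity.
    """
    if t_steps < 1 or n_features < 1:
        raise ValueError("t_steps and n_features must be >= 1")
    if snr < 0:
        raise ValueError("snr must be >= 0")
    idx = np.array([lab.index if isinstance(lab, EmotionLabel) else int(lab) for lab in labels])
    if intensities is None:
        signed = 2.0 * idx - 1.0
    else:
        signed = np.asarray(intensities, dtype=float)
        if signed.shape != idx.shape:
            raise ValueError("one intensity per label required")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(n_features)
    direction /= np.linalg.norm(direction)
    out = []
    for s in signed:
        mean = 0.5 * s * snr * noise_std * direction
        out.append(mean[None, :] + noise_std * rng.standard_normal((t_steps, n_features)))
    return out


def generate_frame_clips(
    labels: list[EmotionLabel] | np.ndarray,
    t_steps: int,
    height: int = 48,
    width: int = 48,
    seed: int = 0,
    slow_speed: float = 1.0,
    fast_speed: float = 6.0,
    noise_std: float = 0.02,
) -> list[VisualClip]:
    """Clips of a drifting Gaussian blob; class 1 drifts faster than class 0.

    The per-frame displacement of the blob centre is the class-dependent
    construction parameter, recoverable from the generated frames.
    """
    if t_steps < 1:
        raise ValueError("t_steps must be >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    sigma = height / 8.0
    clips = []
    for lab in labels:
        label = lab if isinstance(lab, EmotionLabel) else EmotionLabel.from_rating("valence", 8 if int(lab) else 2)
        speed = fast_speed if label.index == 1 else slow_speed
        pos = np.array([rng.uniform(height * 0.3, height * 0.7),
                        rng.uniform(width * 0.3, width * 0.7)])
        angle = rng.uniform(0, 2 * np.pi)
        vel = speed * np.array([np.sin(angle), np.cos(angle)])
        frames = np.empty((t_steps, height, width, 3))
        for t in range(t_steps):
            dy = (yy - pos[0] + height / 2) % height - height / 2
            dx = (xx - pos[1] + width / 2) % width - width / 2
            blob = np.exp(-(dy**2 + dx**2) / (2 * sigma**2))
            # wrap-around distance keeps the blob on-screen under drift
            frame = blob[:, :, None] + noise_std * rng.standard_normal((height, width, 3))
            frames[t] = np.clip(frame, 0.0, 1.0)
            pos = pos + vel
        clips.append(VisualClip(frames=frames, label=label, drift_speed=speed))
    return clips
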
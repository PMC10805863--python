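"""3D EEG feature construction.

A segmented EEG window is decomposed into the four classical frequency
bands -- theta (4-7 Hz), alpha (8-13 Hz), beta (14-30 Hz), gamma (31-50 Hz)
-- with a zero-phase Butterworth filter; the differential entropy (DE) of
each band-limited channel slice is computed under a Gaussian assumption,

    DE = 0.5 * ln(2 * pi * e * sigma^2)   [nats],

and the per-channel values are scattered onto a sparse 9x9 scalp grid that
preserves the relative 10-20 electrode geometry (unoccupied cells are
zero).  Splitting each window into T equal sub-slices and stacking the four
band grids yields the T x B x H x W tensor consumed by the EEG network.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import signal as sps

from .preprocessing import EEGWindow

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "Montage",
    "bandpass_decompose",
    "differential_entropy",
    "gaussian_de",
    "project_to_grid",
    "build_feature_tensor",
    "windows_to_tensors",
    "raw_window_tensor",
]

VAR_FLOOR = 1e-12  # keeps DE finite on degenerate (constant) slices


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")


DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma", 31.0, 50.0),
)


class Montage:
    """Injective map from channel names to cells of an H x W scalp grid."""

    def __init__(self, mapping: dict[str, tuple[int, int]], height: int = 9, width: int = 9):
        self.height = int(height)
        self.width = int(width)
        self.mapping = {str(k): (int(r), int(c)) for k, (r, c) in mapping.items()}
        seen: set[tuple[int, int]] = set()
        for name, (r, c) in self.mapping.items():
            if not (0 <= r < self.height and 0 <= c < self.width):
                raise ValueError(f"channel {name} at ({r}, {c}) outside the {height}x{width} grid")
            if (r, c) in seen:
                raise ValueError(f"duplicate grid cell ({r}, {c}) (channel {name})")
            seen.add((r, c))

    def __len__(self):
        return len(self.mapping)

    def __contains__(self, name: str):
        return name in self.mapping

    @classmethod
    def from_json(cls, path) -> "Montage":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(obj["mapping"], obj.get("height", 9), obj.get("width", 9))

    @classmethod
    def default_32(cls) -> "Montage":
        """The packaged 32-channel 10-20 layout on the 9x9 grid."""
        ref = resources.files("eegemotion.data") / "montage_32ch_9x9.json"
        with resources.as_file(ref) as path:
            return cls.from_json(path)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"height": self.height, "width": self.width,
                 "mapping": {k: list(v) for k, v in self.mapping.items()}},
                fh, indent=2,
            )

    def hash(self) -> str:
        payload = json.dumps(
            {"h": self.height, "w": self.width, "m": sorted(self.mapping.items())},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @property
    def channel_names(self) -> list[str]:
        return list(self.mapping)


def bandpass_decompose(
    data: np.ndarray,
    sampling_rate: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    order: int = 4,
) -> dict[str, np.ndarray]:
    """Zero-phase Butterworth band decomposition of a channels x samples array.

    Forward-backward (``sosfiltfilt``) application keeps each band signal
    time-aligned with the input.
    """
    nyquist = sampling_rate / 2.0
    out: dict[str, np.ndarray] = {}
    for band in bands:
        if band.high >= nyquist:
            raise ValueError(
                f"band {band.name} upper edge {band.high} Hz >= Nyquist {nyquist} Hz"
            )
        sos = sps.butter(order, [band.low, band.high], btype="bandpass", fs=sampling_rate, output="sos")
        out[band.name] = sps.sosfiltfilt(sos, data, axis=-1)
    return out


def gaussian_de(variance) -> np.ndarray:
    """Closed-form differential entropy of a Gaussian with given variance (nats)."""
    return 0.5 * np.log(2.0 * np.pi * np.e * np.asarray(variance, dtype=float))


def differential_entropy(band_signal: np.ndarray, var_floor: float = VAR_FLOOR) -> np.ndarray:
    """Per-channel DE of a channels x samples band-limited slice.

    Uses the Gaussian closed form with the unbiased sample variance; a
    variance floor keeps the result finite on constant slices.
    """
    x = np.asarray(band_signal, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 samples per channel")
    var = x.var(axis=-1, ddof=1)
    return gaussian_de(np.maximum(var, var_floor))


def project_to_grid(
    per_channel_values: np.ndarray,
    channel_names: list[str],
    montage: Montage,
) -> np.ndarray:
    """Scatter per-channel values onto the montage grid; empty cells are 0."""
    values = np.asarray(per_channel_values, dtype=float)
    if values.shape[0] != len(channel_names):
        raise ValueError("one value per channel required")
    grid = np.zeros((montage.height, montage.width))
    for name, v in zip(channel_names, values):
        if name not in montage:
            raise KeyError(f"channel {name!r} not in montage")
        r, c = montage.mapping[name]
        grid[r, c] = v
    return grid


def build_feature_tensor(
    window: EEGWindow,
    t_slices: int,
    channel_names: list[str],
    montage: Montage | None = None,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    filter_order: int = 4,
) -> np.ndarray:
    """Build the T x B x H x W DE tensor for one window.

    The window is band-decomposed once, then cut into ``t_slices`` equal
    non-overlapping sub-slices; per sub-slice and band the channel DE values
    are projected onto the grid.
    """
    montage = montage or Montage.default_32()
    n_samples = window.data.shape[1]
    if t_slices < 1 or n_samples % t_slices != 0:
        raise ValueError(
            f"window of {n_samples} samples not divisible into {t_slices} sub-slices"
        )
    per_band = bandpass_decompose(window.data, window.sampling_rate, bands, filter_order)
    step = n_samples // t_slices
    tensor = np.zeros((t_slices, len(bands), montage.height, montage.width))
    for ti in range(t_slices):
        sl = slice(ti * step, (ti + 1) * step)
        for bi, band in enumerate(bands):
            de = differential_entropy(per_band[band.name][:, sl])
            tensor[ti, bi] = project_to_grid(de, channel_names, montage)
    return tensor


def windows_to_tensors(
    windows,
    t_slices: int,
    channel_names: list[str],
    montage: Montage | None = None,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorise a window list into (N,T,B,H,W) features and 0/1 labels."""
    montage = montage or Montage.default_32()
    feats = np.stack(
        [build_feature_tensor(w, t_slices, channel_names, montage, bands) for w in windows]
    )
    labels = np.array([w.label.index if w.label is not None else -1 for w in windows])
    return feats, labels


def raw_window_tensor(
    window: EEGWindow,
    channel_names: list[str],
    montage: Montage | None = None,
    downsample: int = 1,
) -> np.ndarray:
    """Project raw sampling points straight onto the grid (no DE, no bands).

    Every ``downsample``-th sampling point becomes one time slice of shape
    1 x H x W, giving the raw-input variant used in the ablation study.
    """
    montage = montage or Montage.default_32()
    data = window.data[:, ::downsample]
    t = data.shape[1]
    tensor = np.zeros((t, 1, montage.height, montage.width))
    for ti in range(t):
        tensor[ti, 0] = project_to_grid(data[:, ti], channel_names, montage)
    return tensor
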
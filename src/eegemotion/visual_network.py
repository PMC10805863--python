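"""The visual branch: per-frame CNN + parameter-shared temporal conv network.

Frames (T x 48 x 48 x 3) are encoded independently by a small CNN
(conv-pool-conv-pool-flatten-linear) into T x 512 spatial features.  A 1x1
entry convolution maps the 512 channels to the temporal width, after which
two *fully parameter-shared* temporal convolution modules and a
length-preserving average pool produce the T x 128 spatio-temporal features
V_t used both for classification (per-step linear + softmax to T x 2) and
as the distillation teacher.  Each temporal module is one kernel-3
dilation-1 conv and two kernel-3 dilation-2 convs (ReLU, normalisation and
dropout 0.5 after each), with a 1x1-conv residual path; same padding keeps
the sequence length, giving a receptive field of 11 steps per module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nn import BatchNorm1d, Conv1d, Dropout, Linear, Module, Tensor
from .nn import functional as F

__all__ = ["VisualNetConfig", "TemporalConvModule", "VisualNet", "receptive_field"]


@dataclass(frozen=True)
class VisualNetConfig:
    frame_size: int = 48
    conv_channels: tuple[int, int] = (32, 64)
    fc_dim: int = 512
    tcn_channels: int = 128
    dropout: float = 0.5

    def flatten_dim(self) -> int:
        return (self.frame_size // 4) ** 2 * self.conv_channels[1]

    def small(self, conv=(4, 8), fc=64, tcn=32) -> "VisualNetConfig":
        return replace(self, conv_channels=conv, fc_dim=fc, tcn_channels=tcn)


class TemporalConvModule(Module):
    """conv(k3,d1) -> 2x conv(k3,d2), each relu+norm+dropout, plus 1x1 residual."""

    def __init__(self, n_ch: int, dropout: float, rng: np.random.Generator, drop_rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(n_ch, n_ch, 3, rng, dilation=1)
        self.conv2 = Conv1d(n_ch, n_ch, 3, rng, dilation=2)
        self.conv3 = Conv1d(n_ch, n_ch, 3, rng, dilation=2)
        self.norms = [BatchNorm1d(n_ch) for _ in range(3)]
        self.drops = [Dropout(dropout, drop_rng) for _ in range(3)]
        self.residual = Conv1d(n_ch, n_ch, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv, norm, drop in zip((self.conv1, self.conv2, self.conv3), self.norms, self.drops):
            h = drop(norm(conv(h).relu()))
        return h + self.residual(x)


def receptive_field(kernel_dilations=((3, 1), (3, 2), (3, 2))) -> int:
    """Time steps seen by one temporal module: 1 + sum (k-1)*d."""
    return 1 + sum((k - 1) * d for k, d in kernel_dilations)


class VisualNet(Module):
    def __init__(self, config: VisualNetConfig = VisualNetConfig(), seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        cfg = self.config = config
        from .nn import Conv2d

        self.conv1 = Conv2d(3, cfg.conv_channels[0], 3, rng)
        self.conv2 = Conv2d(cfg.conv_channels[0], cfg.conv_channels[1], 3, rng)
        self.fc = Linear(cfg.flatten_dim(), cfg.fc_dim, rng)
        self.entry = Conv1d(cfg.fc_dim, cfg.tcn_channels, 1, rng)
        # a single module instance applied twice = full parameter sharing
        self.temporal = TemporalConvModule(cfg.tcn_channels, cfg.dropout, rng, drop_rng)
        self.head = Linear(cfg.tcn_channels, 2, rng)

    def cnn_forward(self, frames) -> Tensor:
        """frames: (N, T, H, W, 3) -> spatial features (N, T, fc_dim)."""
        if not isinstance(frames, Tensor):
            frames = Tensor(np.asarray(frames, dtype=float))
        n, t, h, w, c = frames.shape
        if (h, w, c) != (self.config.frame_size, self.config.frame_size, 3):
            raise ValueError(f"expected frames of {self.config.frame_size}x"
                             f"{self.config.frame_size}x3, got {h}x{w}x{c}")
        x = frames.reshape(n * t, h, w, c).transpose(0, 3, 1, 2)
        x = F.maxpool2d(self.conv1(x).relu(), 2, 2)
        x = F.maxpool2d(self.conv2(x).relu(), 2, 2)
        x = x.reshape(n * t, -1)
        return self.fc(x).reshape(n, t, -1)

    def tcn_forward(self, spatial: Tensor) -> Tensor:
        """spatial: (N, T, fc_dim) -> spatio-temporal features (N, T, tcn_channels)."""
        x = spatial.transpose(0, 2, 1)  # (N, C, T)
        x = self.entry(x)
        x = self.temporal(x)
        x = self.temporal(x)
        x = F.avgpool1d_same(x, 2)
        return x.transpose(0, 2, 1)

    def classify(self, vt: Tensor) -> Tensor:
        """vt: (N, T, C) -> per-step class probabilities (N, T, 2)."""
        logits = self.head(vt)
        return (logits - logits.logsumexp(axis=-1, keepdims=True)).exp()

    def forward(self, frames) -> tuple[Tensor, Tensor]:
        """-> (per-step probabilities (N, T, 2), features V_t (N, T, C))."""
        vt = self.tcn_forward(self.cnn_forward(frames))
        return self.classify(vt), vt

    def extract_features(self, frames) -> np.ndarray:
        """Deterministic T x C teacher features (dropout/norm in eval mode)."""
        was_training = self.training
        self.eval()
        try:
            _, vt = self.forward(frames)
        finally:
            if was_training:
                self.train()
        return vt.data
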
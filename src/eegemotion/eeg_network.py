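"""The EEG branch: per-slice CNN, stacked peephole LSTM, attention, classifier.

Input is the T x B x 9 x 9 differential-entropy tensor.  Each time slice is
gated by the (shared) band attention, encoded by a four-layer same-padded
CNN (kernels 5x5, 4x4, 3x3, 1x1; channels 64, 128, 256, 128), max-pooled
2x2/stride 2, and flattened through a fully connected layer to 512
features.  The T slice codes run through a two-layer peephole LSTM (hidden
size 128); the self-attention module reweights the hidden states, and a
linear + softmax head classifies from their sum.  The LSTM's T x 128
hidden-state sequence is also returned as the student feature Vs that the
distillation loss pulls toward the visual teacher (tapping upstream of the
attention weighting keeps the L1 pull from flattening the attention
probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import BandAttention, SelfAttention
from .nn import Linear, Module, PeepholeLSTM, Tensor
from .nn import functional as F

__all__ = ["EEGNetConfig", "EEGNet", "EEGForward"]


@dataclass(frozen=True)
class EEGNetConfig:
    n_bands: int = 4
    grid: int = 9
    conv_channels: tuple[int, ...] = (64, 128, 256, 128)
    conv_kernels: tuple[int, ...] = (5, 4, 3, 1)
    fc_dim: int = 512
    lstm_hidden: int = 128
    lstm_layers: int = 2
    band_attention: bool = True
    self_attention: bool = True

    def flatten_dim(self) -> int:
        # same padding keeps the grid size; one 2x2/stride-2 pool floors it
        return (self.grid // 2) ** 2 * self.conv_channels[-1]

    def small(self, conv=(8, 8, 16, 8), fc=64, hidden=32) -> "EEGNetConfig":
        """Reduced-width copy for CPU-scale training experiments."""
        from dataclasses import replace

        return replace(self, conv_channels=conv, fc_dim=fc, lstm_hidden=hidden)


@dataclass
class EEGForward:
    probs: Tensor  # (N, 2)
    log_probs: Tensor  # (N, 2)
    features: Tensor  # (N, T, hidden) -- the student sequence Vs (LSTM output)
    attended: Tensor  # (N, T, hidden) -- attention-weighted states
    band_weights: np.ndarray | None  # (N, T, B)


class EEGNet(Module):
    def __init__(self, config: EEGNetConfig = EEGNetConfig(), seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        cfg = config
        if cfg.band_attention:
            self.band_attention = BandAttention(cfg.n_bands, rng)
        chans = (cfg.n_bands,) + cfg.conv_channels
        from .nn import Conv2d

        self.convs = [
            Conv2d(chans[i], chans[i + 1], cfg.conv_kernels[i], rng)
            for i in range(len(cfg.conv_channels))
        ]
        self.fc = Linear(cfg.flatten_dim(), cfg.fc_dim, rng)
        self.lstm = PeepholeLSTM(cfg.fc_dim, cfg.lstm_hidden, cfg.lstm_layers, rng)
        if cfg.self_attention:
            self.self_attention = SelfAttention(cfg.lstm_hidden, rng)
        self.head = Linear(cfg.lstm_hidden, 2, rng)

    # -- pieces ----------------------------------------------------------
    def cnn_forward(self, x: Tensor) -> Tensor:
        """x: (N, B, H, W) -> (N, fc_dim)."""
        if x.shape[1:] != (self.config.n_bands, self.config.grid, self.config.grid):
            raise ValueError(f"expected (*, {self.config.n_bands}, {self.config.grid}, "
                             f"{self.config.grid}), got {x.shape}")
        h = x
        for conv in self.convs:
            h = conv(h).relu()
        h = F.maxpool2d(h, 2, 2)
        h = h.reshape(h.shape[0], -1)
        return self.fc(h)

    def classify(self, attended: Tensor) -> tuple[Tensor, Tensor]:
        """attended: (N, T, hidden) -> (probs, log_probs), pooling by sum over t."""
        pooled = attended.sum(axis=1)
        logits = self.head(pooled)
        log_probs = logits - logits.logsumexp(axis=-1, keepdims=True)
        return log_probs.exp(), log_probs

    # -- full branch -----------------------------------------------------
    def forward(self, x) -> EEGForward:
        """x: (N, T, B, H, W) array or Tensor."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=float))
        n, t = x.shape[0], x.shape[1]
        flat = x.reshape(n * t, *x.shape[2:])
        band_w = None
        if self.config.band_attention:
            weights, flat = self.band_attention(flat)
            band_w = weights.data.reshape(n, t, -1)
        codes = self.cnn_forward(flat).reshape(n, t, -1)
        hidden = self.lstm(codes)
        if self.config.self_attention:
            _, attended = self.self_attention(hidden)
        else:
            attended = hidden * (1.0 / t)  # uniform probabilities
        probs, log_probs = self.classify(attended)
        return EEGForward(probs=probs, log_probs=log_probs, features=hidden,
                          attended=attended, band_weights=band_w)
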
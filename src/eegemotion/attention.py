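"""Frequency-band attention and time-step self-attention.

Band attention follows the efficient-channel-attention pattern: the B x H x
W feature map is global-average-pooled to one descriptor per band, a 1-D
convolution of adaptively chosen odd kernel size mixes neighbouring bands,
and a sigmoid yields one gate in (0, 1) per band that rescales the map.

Self-attention scores each LSTM hidden state h_t with an additive form

    S_t = W_t . relu(W_1 h_t + W_2 d_t + b_1) + b_2,      d_t = W_d h_t,

reduces it to a scalar similarity N_t = S_t . h_t, softmaxes over time, and
reweights the hidden states with the resulting probabilities.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, Module, Linear, glorot_uniform
from .nn import functional as F

__all__ = ["adaptive_kernel_size", "BandAttention", "SelfAttention"]


def adaptive_kernel_size(c: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Odd 1-D kernel size from the band count: nearest odd to log2(c)/gamma + b/gamma.

    Ties round toward the smaller odd value; the minimum is 1.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    t = np.log2(c) / gamma + b / gamma
    k_low = max(1, 2 * int((t - 1) // 2) + 1)
    k_high = k_low + 2
    k = k_low if (t - k_low) <= (k_high - t) else k_high
    return max(1, k)


class BandAttention(Module):
    """Per-band sigmoid gate from a 1-D conv over pooled band descriptors.

    The conv weight is shared across time slices and initialised with a
    positive magnitude so the gate opens toward high-energy bands at the
    start of training (symmetry breaking for the scalar-kernel case).
    """

    def __init__(self, n_bands: int, rng: np.random.Generator, gamma: float = 2.0, b: float = 1.0):
        super().__init__()
        self.n_bands = n_bands
        self.kernel_size = adaptive_kernel_size(n_bands, gamma, b)
        w = glorot_uniform(rng, (1, 1, self.kernel_size), self.kernel_size, self.kernel_size)
        self.w = Tensor(np.abs(w), requires_grad=True)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """x: (N, B, H, W) -> (weights (N, B), weighted map (N, B, H, W))."""
        if x.shape[1] != self.n_bands:
            raise ValueError(f"expected {self.n_bands} bands, got {x.shape[1]}")
        pooled = x.mean(axis=(2, 3))  # (N, B)
        mixed = F.conv1d(pooled.reshape(x.shape[0], 1, self.n_bands), self.w)
        weights = mixed.reshape(x.shape[0], self.n_bands).sigmoid()
        weighted = x * weights.reshape(x.shape[0], self.n_bands, 1, 1)
        return weights, weighted


class SelfAttention(Module):
    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.align = Linear(d, d, rng, bias=False)  # d_t = W_d h_t
        self.w1 = Linear(d, d, rng)  # carries b_1
        self.w2 = Linear(d, d, rng, bias=False)
        self.wt = Linear(d, d, rng)  # carries b_2

    def scores(self, h: Tensor) -> Tensor:
        """h: (N, T, d) -> per-step score vectors S: (N, T, d)."""
        d_t = self.align(h)
        return self.wt((self.w1(h) + self.w2(d_t)).relu())

    def probabilities(self, s: Tensor, h: Tensor) -> tuple[Tensor, Tensor]:
        """Similarities N_t = S_t . h_t and their softmax over time."""
        n_t = (s * h).sum(axis=-1)  # (N, T)
        return n_t, n_t.softmax(axis=-1)

    @staticmethod
    def apply(h: Tensor, p: Tensor) -> Tensor:
        """A_t = P_t * h_t."""
        return h * p.reshape(p.shape[0], p.shape[1], 1)

    def forward(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """h: (N, T, d) -> (probabilities (N, T), attended features (N, T, d))."""
        s = self.scores(h)
        _, p = self.probabilities(s, h)
        return p, self.apply(h, p)
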
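"""Layers, parameter containers, and the Adam optimiser."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, stack
from . import functional as F

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "Conv1d",
    "BatchNorm1d",
    "Dropout",
    "PeepholeLSTM",
    "Adam",
    "glorot_uniform",
    "orthogonal",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, shape) -> np.ndarray:
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    return q if shape[0] >= shape[1] else q.T


class Module:
    """Minimal module container: tracks parameters and train/eval mode."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = ""):
        """Non-learnable state (e.g. normalisation running stats)."""
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(own) | set(buffers)) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in state.items():
            target = own[k].data if k in own else buffers[k]
            if target.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            target[...] = v

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.w = Tensor(glorot_uniform(rng, (in_features, out_features), in_features, out_features), requires_grad=True)
        self.b = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y if self.b is None else y + self.b


class Conv2d(Module):
    """Same-padded stride-1 2-D convolution layer."""

    def __init__(self, in_ch: int, out_ch: int, kernel, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan_in, fan_out = in_ch * kh * kw, out_ch * kh * kw
        self.w = Tensor(glorot_uniform(rng, (out_ch, in_ch, kh, kw), fan_in, fan_out), requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.w, self.b)


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator, bias: bool = True, dilation: int = 1):
        super().__init__()
        fan_in, fan_out = in_ch * k, out_ch * k
        self.w = Tensor(glorot_uniform(rng, (out_ch, in_ch, k), fan_in, fan_out), requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return F.conv1d(x, self.w, self.b, dilation=self.dilation)


class BatchNorm1d(Module):
    """Per-channel normalisation over (N, C, L) activations."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self._buffers = ("running_mean", "running_var")
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            centered = x - mu
            var = (centered ** 2.0).mean(axis=(0, 2), keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
            xhat = centered * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean[None, :, None]
            var = self.running_var[None, :, None]
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class _LSTMLayer(Module):
    """Single peephole LSTM layer (gates receive the cell state)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        super().__init__()
        def inp(shape):
            return Tensor(glorot_uniform(rng, shape, shape[0], shape[1]), requires_grad=True)

        def rec(shape):
            return Tensor(orthogonal(rng, shape), requires_grad=True)

        h = d_hidden
        self.w_yi, self.w_hi, self.w_ci = inp((d_in, h)), rec((h, h)), rec((h, h))
        self.w_yf, self.w_hf, self.w_cf = inp((d_in, h)), rec((h, h)), rec((h, h))
        self.w_yc, self.w_hc = inp((d_in, h)), rec((h, h))
        self.w_yo, self.w_ho, self.w_co = inp((d_in, h)), rec((h, h)), rec((h, h))
        # forget-gate bias 1: standard trick to keep memory open early in training
        self.b_i = Tensor(np.zeros(h), requires_grad=True)
        self.b_f = Tensor(np.ones(h), requires_grad=True)
        self.b_c = Tensor(np.zeros(h), requires_grad=True)
        self.b_o = Tensor(np.zeros(h), requires_grad=True)
        self.d_hidden = h

    def forward(self, xs: Tensor) -> Tensor:
        """xs: (N, T, d_in) -> hidden states (N, T, d_hidden)."""
        n, t_steps, _ = xs.shape
        h = Tensor(np.zeros((n, self.d_hidden)))
        c = Tensor(np.zeros((n, self.d_hidden)))
        hs = []
        for t in range(t_steps):
            y = xs[:, t, :]
            i = (y @ self.w_yi + h @ self.w_hi + c @ self.w_ci + self.b_i).sigmoid()
            f = (y @ self.w_yf + h @ self.w_hf + c @ self.w_cf + self.b_f).sigmoid()
            c = f * c + i * (y @ self.w_yc + h @ self.w_hc + self.b_c).tanh()
            o = (y @ self.w_yo + h @ self.w_ho + c @ self.w_co + self.b_o).sigmoid()
            h = o * c.tanh()
            hs.append(h)
        return stack(hs, axis=1)


class PeepholeLSTM(Module):
    """Stacked peephole LSTM returning all top-layer hidden states."""

    def __init__(self, d_in: int, d_hidden: int, n_layers: int, rng: np.random.Generator):
        super().__init__()
        self.layers = [
            _LSTMLayer(d_in if i == 0 else d_hidden, d_hidden, rng) for i in range(n_layers)
        ]

    def forward(self, xs: Tensor) -> Tensor:
        for layer in self.layers:
            xs = layer(xs)
        return xs


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
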
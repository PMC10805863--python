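"""Convolution and pooling primitives for the autodiff engine.

All convolutions are stride-1 with zero ("same") padding, which is the only
configuration the networks here use; pooling is the 2x2/stride-2 max pool
of the EEG CNN and a length-preserving average pool for the temporal
network.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = ["conv2d", "conv1d", "maxpool2d", "avgpool1d_same"]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 2-D convolution.

    Parameters
    ----------
    x : Tensor, shape (N, C, H, W)
    w : Tensor, shape (O, C, kh, kw)
    b : Tensor, shape (O,), optional
    """
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    ph0, ph1 = (kh - 1) // 2, kh // 2
    pw0, pw1 = (kw - 1) // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph0, ph1), (pw0, pw1)))
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    out_data = np.einsum("nchwij,ocij->nohw", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._from_op(out_data, parents, None)

    def bw(g):
        if w.requires_grad:
            w._accumulate(np.einsum("nchwij,nohw->ocij", cols, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + h, j : j + wd] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True
                    )
            x._accumulate(gxp[:, :, ph0 : ph0 + h, pw0 : pw0 + wd])

    out._backward = bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Same-padded stride-1 1-D convolution with optional dilation.

    Parameters
    ----------
    x : Tensor, shape (N, C, L)
    w : Tensor, shape (O, C, k)
    """
    n, c, length = x.shape
    o, c2, k = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    span = (k - 1) * dilation  # extra length covered by the kernel
    p0, p1 = span // 2, span - span // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p0, p1)))
    out_data = np.zeros((n, o, length))
    for j in range(k):
        out_data += np.einsum("ncl,oc->nol", xp[:, :, j * dilation : j * dilation + length], w.data[:, :, j], optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._from_op(out_data, parents, None)

    def bw(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for j in range(k):
                gw[:, :, j] = np.einsum(
                    "ncl,nol->oc", xp[:, :, j * dilation : j * dilation + length], g, optimize=True
                )
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, :, j * dilation : j * dilation + length] += np.einsum(
                    "nol,oc->ncl", g, w.data[:, :, j], optimize=True
                )
            x._accumulate(gxp[:, :, p0 : p0 + length])

    out._backward = bw
    return out


def maxpool2d(x: Tensor, k: int = 2, stride: int = 2) -> Tensor:
    """Max pooling; trailing rows/columns not filling a window are dropped."""
    if k != stride:
        raise NotImplementedError("only k == stride pooling is used here")
    n, c, h, w = x.shape
    ho, wo = h // k, w // k
    xc = x.data[:, :, : ho * k, : wo * k].reshape(n, c, ho, k, wo, k)
    out_data = xc.max(axis=(3, 5))
    # argmax mask for routing gradients
    mask = xc == out_data[:, :, :, None, :, None]
    # break ties: keep only first max per window
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
    first = np.zeros_like(flat)
    idx = flat.argmax(axis=-1)
    np.put_along_axis(first, idx[..., None], 1, axis=-1)
    mask = first.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
    out = Tensor._from_op(out_data, (x,), None)

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        expanded = mask * g[:, :, :, None, :, None]
        gx[:, :, : ho * k, : wo * k] = expanded.reshape(n, c, ho * k, wo * k)
        x._accumulate(gx)

    out._backward = bw
    return out


def avgpool1d_same(x: Tensor, k: int = 2) -> Tensor:
    """Stride-1 average pool along the last axis, zero-padded to keep length."""
    length = x.shape[-1]
    pad_width = [(0, 0)] * (x.ndim - 1) + [((k - 1) // 2, k // 2)]
    xp = x.pad(tuple(pad_width))
    sl = [slice(None)] * x.ndim
    acc = None
    for j in range(k):
        sl[-1] = slice(j, j + length)
        term = xp[tuple(sl)]
        acc = term if acc is None else acc + term
    return acc * (1.0 / k)
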
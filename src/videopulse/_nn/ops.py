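"""Differentiable layer primitives: 2-D/1-D convolutions, causal FIR taps,
pooling and dense maps.

Convolutions use im2col + BLAS matmul; kernels are odd-sized with 'same'
zero padding.  The causal FIR op is the temporal filtering primitive the
filtering modules are built from: left-padded so output[t] depends only on
input[max(t-K,0)..t].
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor


def _im2col2d(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """x: (N,H,W,C) zero-padded 'same' -> (N*H*W, kh*kw*C)."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H,W,C,kh,kw)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(n * h * w, kh * kw * c)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same' 2-D convolution (cross-correlation) over (N,H,W,Cin).

    w: (kh,kw,Cin,Cout), b: (Cout,).
    """
    n, h, wd, cin = x.data.shape
    kh, kw, _, cout = w.data.shape
    cols = _im2col2d(x.data, kh, kw)
    out = (cols @ w.data.reshape(kh * kw * cin, cout) + b.data).reshape(n, h, wd, cout)

    def backward(g):
        gf = g.reshape(n * h * wd, cout)
        if w.requires_grad:
            w._accumulate((cols.T @ gf).reshape(kh, kw, cin, cout))
        if b.requires_grad:
            b._accumulate(gf.sum(axis=0))
        if x.requires_grad:
            # full correlation of g with spatially flipped, transposed kernel
            wflip = w.data[::-1, ::-1].transpose(0, 1, 3, 2)  # (kh,kw,Cout,Cin)
            gcols = _im2col2d(g.reshape(n, h, wd, cout), kh, kw)
            dx = (gcols @ wflip.reshape(kh * kw * cout, cin)).reshape(n, h, wd, cin)
            x._accumulate(dx)

    return Tensor._make(out, (x, w, b), backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same' temporal convolution over (B,T,Cin); w: (k,Cin,Cout)."""
    bt, t, cin = x.data.shape
    k, _, cout = w.data.shape
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    win = sliding_window_view(xp, k, axis=1)  # (B,T,Cin,k)
    cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(bt * t, k * cin)
    out = (cols @ w.data.reshape(k * cin, cout) + b.data).reshape(bt, t, cout)

    def backward(g):
        gf = g.reshape(bt * t, cout)
        if w.requires_grad:
            w._accumulate((cols.T @ gf).reshape(k, cin, cout))
        if b.requires_grad:
            b._accumulate(gf.sum(axis=0))
        if x.requires_grad:
            wflip = w.data[::-1].transpose(0, 2, 1)  # (k,Cout,Cin)
            gp = np.pad(g.reshape(bt, t, cout), ((0, 0), (pad, pad), (0, 0)))
            gwin = sliding_window_view(gp, k, axis=1)
            gcols = np.ascontiguousarray(gwin.transpose(0, 1, 3, 2)).reshape(bt * t, k * cout)
            dx = (gcols @ wflip.reshape(k * cout, cin)).reshape(bt, t, cin)
            x._accumulate(dx)

    return Tensor._make(out, (x, w, b), backward)


def fir_causal(x: Tensor, h: Tensor, padding: str = "causal-replicate") -> Tensor:
    """Per-channel causal FIR along the time axis of (B,T,C).

    h: (C, K+1) with h[:, k] the tap applied to x[t-k].  y[t] = sum_k h[k] x[t-k];
    samples before t=0 are the first frame (causal-replicate) or zero (causal-zero).
    """
    bt, t, c = x.data.shape
    k1 = h.data.shape[1]
    kk = k1 - 1
    if padding == "causal-replicate":
        left = np.repeat(x.data[:, :1, :], kk, axis=1) if kk else x.data[:, :0, :]
    elif padding == "causal-zero":
        left = np.zeros((bt, kk, c), dtype=x.data.dtype)
    else:
        raise ValueError(f"unknown padding {padding!r}")
    xp = np.concatenate([left, x.data], axis=1)  # (B,T+K,C)
    win = sliding_window_view(xp, k1, axis=1)  # (B,T,C,K+1); win[...,j] = x[t-K+j]
    h_rev = h.data[:, ::-1]  # h_rev[:, j] multiplies x[t-K+j]
    out = np.einsum("btck,ck->btc", win, h_rev, optimize=True)

    def backward(g):
        if h.requires_grad:
            dh_rev = np.einsum("btck,btc->ck", win, g, optimize=True)
            h._accumulate(dh_rev[:, ::-1])
        if x.requires_grad:
            # dxp[i] = sum_k h[k] g[i+k-K] over valid g indices
            gp = np.pad(g, ((0, 0), (kk, kk), (0, 0)))
            gwin = sliding_window_view(gp, k1, axis=1)  # (B,T+K,C,K+1)
            dxp = np.einsum("btck,ck->btc", gwin, h.data, optimize=True)
            dx = dxp[:, kk:, :].copy()
            if kk and padding == "causal-replicate":
                dx[:, 0, :] += dxp[:, :kk, :].sum(axis=1)
            x._accumulate(dx)

    return Tensor._make(out, (x, h), backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k-by-k average pooling; H and W must divide by k."""
    n, h, w, c = x.data.shape
    if h % k or w % k:
        raise ValueError(f"pooling size {k} does not divide spatial dims {(h, w)}")
    out = x.data.reshape(n, h // k, k, w // k, k, c).mean(axis=(2, 4))

    def backward(g):
        if x.requires_grad:
            gg = np.broadcast_to(
                g[:, :, None, :, None, :], (n, h // k, k, w // k, k, c)
            ).reshape(n, h, w, c) / (k * k)
            x._accumulate(gg)

    return Tensor._make(out, (x,), backward)


def spatial_mean(x: Tensor) -> Tensor:
    """(N,H,W,C) -> (N,C) global average over space."""
    return x.mean(axis=(1, 2))


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map on the trailing axis: (..., Cin) @ (Cin, Cout) + (Cout,)."""
    out = x.data @ w.data + b.data
    lead = x.data.shape[:-1]
    cin, cout = w.data.shape

    def backward(g):
        gf = g.reshape(-1, cout)
        xf = x.data.reshape(-1, cin)
        if w.requires_grad:
            w._accumulate(xf.T @ gf)
        if b.requires_grad:
            b._accumulate(gf.sum(axis=0))
        if x.requires_grad:
            x._accumulate((gf @ w.data.T).reshape(*lead, cin))

    return Tensor._make(out, (x, w, b), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a fixed target array."""
    diff = pred - Tensor(np.asarray(target, dtype=pred.data.dtype))
    return (diff * diff).mean()
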
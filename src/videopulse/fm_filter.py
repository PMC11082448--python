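"""Temporal FIR filtering modules (FMs).

The central primitive of the package: a causal finite-impulse-response
filter along the time axis, y[t] = sum_{k=0..K} h(k) x[t-k], usable both as
a standalone signal filter (per channel or per pixel) and — through
:class:`FMLayer` — as a learnable network layer whose taps are trained like
any other convolution kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._nn import Tensor, ops

__all__ = ["FIRFilterBank", "apply_fir", "FMLayer", "fm_layer", "frequency_response"]


@dataclass
class FIRFilterBank:
    """Impulse responses h(k), k = 0..K.

    mode 'shared': coeffs (channels, K+1), one response per channel shared
    over space.  mode 'pixelwise': coeffs (H, W, channels, K+1), one
    response per pixel and channel.  padding: 'causal-replicate' repeats the
    first sample before t=0; 'causal-zero' pads with zeros.
    """

    coeffs: np.ndarray
    mode: str = "shared"
    padding: str = "causal-replicate"

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if self.mode not in ("shared", "pixelwise"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.padding not in ("causal-replicate", "causal-zero"):
            raise ValueError(f"unknown padding {self.padding!r}")
        expected = 2 if self.mode == "shared" else 4
        if self.coeffs.ndim != expected:
            raise ValueError(
                f"{self.mode} mode needs {expected}-D coeffs, got {self.coeffs.ndim}-D"
            )
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("filter coefficients must be finite")

    @property
    def order(self) -> int:
        """K: the number of past taps."""
        return self.coeffs.shape[-1] - 1

    @classmethod
    def identity(cls, channels: int = 1, order: int = 0, **kw) -> "FIRFilterBank":
        h = np.zeros((channels, order + 1))
        h[:, 0] = 1.0
        return cls(h, mode="shared", **kw)


def apply_fir(x: np.ndarray, bank: FIRFilterBank) -> np.ndarray:
    """Causal per-channel (or per-pixel) FIR filtering along axis 0.

    x is (T,) or (T, channels) in shared mode — any extra middle axes are
    broadcast — and (T, H, W, channels) in pixelwise mode.  Output has the
    shape and length of x; y[t] depends only on x[<=t].
    """
    x = np.asarray(x, dtype=np.float64)
    squeeze = False
    if bank.mode == "shared" and x.ndim == 1:
        x = x[:, None]
        squeeze = True
    ch = bank.coeffs.shape[-2] if bank.mode == "pixelwise" else bank.coeffs.shape[0]
    if x.shape[-1] != ch:
        raise ValueError(f"input channels {x.shape[-1]} do not match bank channels {ch}")
    if bank.mode == "pixelwise" and x.shape[1:] != bank.coeffs.shape[:-1]:
        raise ValueError(
            f"pixelwise bank {bank.coeffs.shape[:-1]} does not match frames {x.shape[1:]}"
        )
    k = bank.order
    if k == 0:
        pad = x
    elif bank.padding == "causal-replicate":
        pad = np.concatenate([np.repeat(x[:1], k, axis=0), x], axis=0)
    else:
        pad = np.concatenate([np.zeros((k,) + x.shape[1:]), x], axis=0)
    win = sliding_window_view(pad, k + 1, axis=0)  # (T, ..., K+1); [..., j] = x[t-K+j]
    rev = bank.coeffs[..., ::-1]
    out = np.einsum("t...k,...k->t...", win, rev, optimize=True)
    return out[:, 0] if squeeze else out


class FMLayer:
    """Learnable filtering module: per-channel causal FIR taps.

    Initialized as a near-identity response (h(0)=1 plus uniform noise of
    scale `init_noise`) so an untrained FM starts as a pass-through and
    training shapes the frequency response.
    """

    def __init__(
        self,
        channels: int,
        order: int = 3,
        init_noise: float = 0.01,
        padding: str = "causal-replicate",
        rng: np.random.Generator | None = None,
    ):
        if channels < 1 or order < 0:
            raise ValueError("channels must be >= 1 and order >= 0")
        rng = rng or np.random.default_rng()
        h = np.zeros((channels, order + 1))
        h[:, 0] = 1.0
        if init_noise:
            h += rng.uniform(-init_noise, init_noise, size=h.shape)
        self.taps = Tensor(h, requires_grad=True)
        self.padding = padding

    @property
    def order(self) -> int:
        return self.taps.data.shape[1] - 1

    def set_identity(self) -> None:
        self.taps.data[:] = 0.0
        self.taps.data[:, 0] = 1.0

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, C) -> filtered (B, T, C)."""
        return ops.fir_causal(x, self.taps, padding=self.padding)

    def as_bank(self) -> FIRFilterBank:
        return FIRFilterBank(self.taps.data.copy(), mode="shared", padding=self.padding)


def fm_layer(
    channels: int,
    order: int = 3,
    init: str = "identity-noise",
    rng: np.random.Generator | None = None,
    padding: str = "causal-replicate",
) -> FMLayer:
    """Build a learnable FM layer; `init` 'identity' gives exact pass-through."""
    noise = 0.0 if init == "identity" else 0.01
    return FMLayer(channels, order=order, init_noise=noise, padding=padding, rng=rng)


def frequency_response(
    bank: FIRFilterBank, fps: float, n_freq: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Complex gain H(f) = sum_k h(k) exp(-i 2 pi f k / fps) on [0, fps/2].

    Returns (freqs_hz, gains) with gains shaped like coeffs[..., :n_freq]
    (one response per channel, or per pixel and channel).
    """
    if n_freq < 2:
        raise ValueError("n_freq must be >= 2")
    freqs = np.linspace(0.0, fps / 2.0, n_freq)
    k = np.arange(bank.coeffs.shape[-1])
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / fps)  # (n_freq, K+1)
    gains = bank.coeffs @ phase.T  # (..., n_freq)
    return freqs, gains
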
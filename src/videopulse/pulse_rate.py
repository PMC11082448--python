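"""Band-pass filtering and FFT spectral-peak heart-rate estimation.

The physiological band defaults to 0.66–3.0 Hz (40–180 bpm).  Heart rate is
the frequency of the largest magnitude-spectrum bin inside the band, on a
mean-removed, zero-padded window; ties break toward the lower frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io_media import BVPWaveform

__all__ = ["HREstimate", "UndefinedHRError", "bandpass", "estimate_hr", "hr_series",
           "DEFAULT_BAND"]

DEFAULT_BAND = (0.66, 3.0)  # Hz; 40–180 bpm


class UndefinedHRError(ValueError):
    """Raised when a waveform carries no spectral content to rate."""


@dataclass
class HREstimate:
    bpm: float
    window_index: int = 0
    peak_power_fraction: float = 1.0


def bandpass(w: BVPWaveform, low: float = DEFAULT_BAND[0],
             high: float = DEFAULT_BAND[1]) -> BVPWaveform:
    """Zero-phase Butterworth band-pass (order 3, forward-backward)."""
    nyq = w.fps / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz must sit inside (0, {nyq}) Hz")
    sos = signal.butter(3, [low, high], btype="bandpass", fs=w.fps, output="sos")
    out = signal.sosfiltfilt(sos, w.samples)
    return replace(w, samples=out)


def estimate_hr(
    w: BVPWaveform,
    band: tuple[float, float] = DEFAULT_BAND,
    zero_pad_factor: int = 4,
    window_index: int = 0,
) -> HREstimate:
    """Spectral-peak heart rate of one waveform window.

    bpm = 60 x argmax_f |FFT| over the physiological band, after mean
    removal and zero padding to `zero_pad_factor` x the window length.
    """
    if w.duration_s < 2.0:
        raise ValueError("need at least 2 s of samples for a rate estimate")
    if zero_pad_factor < 1:
        raise ValueError("zero_pad_factor must be >= 1")
    x = w.samples - w.samples.mean()
    if np.allclose(x, 0.0):
        raise UndefinedHRError("waveform has no variation; heart rate undefined")
    n = w.n_samples * zero_pad_factor
    spec = np.abs(np.fft.rfft(x, n=n))
    freqs = np.fft.rfftfreq(n, d=1.0 / w.fps)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError(f"band {band} Hz contains no spectral bins at fps {w.fps}")
    power = spec**2
    band_power = np.where(in_band, power, 0.0)
    peak = int(np.argmax(band_power))  # first occurrence = lower frequency on ties
    total = band_power.sum()
    if total <= 0:
        raise UndefinedHRError("no in-band energy; heart rate undefined")
    return HREstimate(
        bpm=60.0 * freqs[peak],
        window_index=window_index,
        peak_power_fraction=float(power[peak] / total),
    )


def hr_series(
    w: BVPWaveform,
    window: int = 256,
    band: tuple[float, float] = DEFAULT_BAND,
    zero_pad_factor: int = 4,
) -> list[HREstimate]:
    """Per-window heart rates over a long waveform (non-overlapping windows)."""
    if w.n_samples < window:
        raise ValueError(f"waveform shorter than one window of {window} samples")
    out = []
    for idx, start in enumerate(range(0, w.n_samples - window + 1, window)):
        chunk = BVPWaveform(w.samples[start : start + window], fps=w.fps, role=w.role)
        out.append(estimate_hr(chunk, band=band, zero_pad_factor=zero_pad_factor,
                               window_index=idx))
    return out
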
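"""Classical rPPG pulse extractors operating on spatially averaged RGB traces.

GREEN (band-passed green channel), CHROM (fixed chrominance projection with
Hann overlap-add), POS (plane-orthogonal-to-skin sliding projection), PBV
(blood-volume-signature weighting), LGI (local group invariance via removal
of the dominant singular direction) and ICA (negentropy-maximizing blind
source separation).  Every extractor ends with the same band-pass and
standardization as the network output so downstream metrics compare
like for like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .io_media import BVPWaveform, FrameSequence
from .pulse_rate import DEFAULT_BAND, bandpass

__all__ = [
    "RGBTrace",
    "roi_trace",
    "green",
    "chrom",
    "pos",
    "pbv",
    "lgi",
    "ica_method",
    "BASELINES",
    "run_baseline",
    "DEFAULT_PBV_SIGNATURE",
]

log = logging.getLogger(__name__)

# relative pulsatile amplitude of the blood-volume pulse in R, G, B
DEFAULT_PBV_SIGNATURE = (0.33, 0.77, 0.53)


@dataclass
class RGBTrace:
    """Spatial-mean channel intensities over time, (T, 3)."""

    values: np.ndarray
    fps: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError(f"trace must be (T,3), got {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")


def roi_trace(fs: FrameSequence, crop_fraction: float = 0.6) -> RGBTrace:
    """Per-frame channel means over a centered crop of each frame.

    crop_fraction is the retained fraction of each spatial dimension;
    1.0 keeps the full frame.
    """
    if not 0 < crop_fraction <= 1:
        raise ValueError("crop_fraction must lie in (0, 1]")
    _, h, w, _ = fs.frames.shape
    ch = max(1, int(round(h * crop_fraction)))
    cw = max(1, int(round(w * crop_fraction)))
    y0, x0 = (h - ch) // 2, (w - cw) // 2
    crop = fs.frames[:, y0 : y0 + ch, x0 : x0 + cw, :]
    return RGBTrace(crop.mean(axis=(1, 2)), fps=fs.fps)


def _finish(x: np.ndarray, fps: float, band: tuple[float, float]) -> BVPWaveform:
    """Shared post-processing: standardize, band-pass, re-standardize."""
    x = np.asarray(x, dtype=np.float64)
    sd = x.std()
    if sd < 1e-12 * max(1.0, abs(float(x.mean()))):
        # zero-variance guard: no variation, no pulse
        return BVPWaveform(np.zeros_like(x), fps=fps, role="estimated")
    x = (x - x.mean()) / sd
    out = bandpass(BVPWaveform(x, fps=fps, role="estimated"), *band).samples
    sd2 = out.std()
    if sd2 > 0:
        out = (out - out.mean()) / sd2
    return BVPWaveform(out, fps=fps, role="estimated")


def green(trace: RGBTrace, band: tuple[float, float] = DEFAULT_BAND) -> BVPWaveform:
    """Band-passed, standardized green channel."""
    return _finish(trace.values[:, 1], trace.fps, band)


def chrom(
    trace: RGBTrace,
    band: tuple[float, float] = DEFAULT_BAND,
    win_seconds: float = 1.6,
) -> BVPWaveform:
    """Chrominance projection with Hann-weighted 50%-overlap-add windows.

    Within each window channels are normalized by their temporal means,
    projected onto X = 3R - 2G and Y = 1.5R + G - 1.5B, and combined as
    S = X - (sd X / sd Y) Y.
    """
    c = trace.values
    t = c.shape[0]
    l = min(t, max(4, int(round(win_seconds * trace.fps))))
    if l % 2:
        l += 1 if l < t else -1
    hop = l // 2
    hann = np.hanning(l)
    out = np.zeros(t)
    for start in range(0, t - l + 1, hop):
        w = c[start : start + l]
        mean = w.mean(axis=0)
        if np.any(mean == 0):
            continue
        rn, gn, bn = (w / mean).T
        x = 3.0 * rn - 2.0 * gn
        y = 1.5 * rn + gn - 1.5 * bn
        sy = y.std()
        if sy == 0:  # degenerate window carries no chrominance
            continue
        s = x - (x.std() / sy) * y
        out[start : start + l] += hann * (s - s.mean())
    return _finish(out, trace.fps, band)


def pos(
    trace: RGBTrace,
    band: tuple[float, float] = DEFAULT_BAND,
    win_seconds: float = 1.6,
) -> BVPWaveform:
    """Plane-orthogonal-to-skin projection with per-sample overlap-add.

    Sliding windows are normalized by their temporal means and projected
    onto S1 = G - B and S2 = G + B - 2R; h = S1 + (sd S1 / sd S2) S2 is
    mean-removed and accumulated at the window position.
    """
    c = trace.values
    t = c.shape[0]
    l = min(t, max(4, int(round(win_seconds * trace.fps))))
    out = np.zeros(t)
    for end in range(l, t + 1):
        w = c[end - l : end]
        mean = w.mean(axis=0)
        if np.any(mean == 0):
            continue
        rn, gn, bn = (w / mean).T
        s1 = gn - bn
        s2 = gn + bn - 2.0 * rn
        sd2 = s2.std()
        h = s1 + (s1.std() / sd2) * s2 if sd2 > 0 else s1
        out[end - l : end] += h - h.mean()
    return _finish(out, trace.fps, band)


def pbv(
    trace: RGBTrace,
    pbv_vector: tuple[float, float, float] = DEFAULT_PBV_SIGNATURE,
    band: tuple[float, float] = DEFAULT_BAND,
    ridge: float = 1e-9,
) -> BVPWaveform:
    """Blood-volume-signature weighting.

    On mean-normalized channels C_n (3, T), the weights solve
    (C_n C_n^T) w = pbv, so w^T C_n is the component whose channel signature
    matches the blood-volume direction while motion-induced distortions,
    which have different signatures, are suppressed.
    """
    c = trace.values
    mean = c.mean(axis=0)
    if np.any(mean == 0):
        raise ValueError("a channel has zero mean; cannot normalize")
    cn = (c / mean - 1.0).T  # (3, T)
    q = cn @ cn.T
    pv = np.asarray(pbv_vector, dtype=np.float64)
    pv = pv / np.linalg.norm(pv)
    w = np.linalg.solve(q + ridge * np.eye(3), pv)
    return _finish(w @ cn, trace.fps, band)


def _band_peak_power(x: np.ndarray, fps: float, band: tuple[float, float]) -> float:
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x, n=4 * x.size)) ** 2
    freqs = np.fft.rfftfreq(4 * x.size, d=1.0 / fps)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(spec[sel].max()) if sel.any() else 0.0


def lgi(trace: RGBTrace, band: tuple[float, float] = DEFAULT_BAND) -> BVPWaveform:
    """Local group invariance: project out the dominant singular direction.

    The leading left singular vector u of the mean-centered (3, T) trace
    captures the dominant (typically illumination/motion) variation;
    P = I - u u^T removes it and the most pulse-energetic remaining
    component is returned.
    """
    c = trace.values.T - trace.values.T.mean(axis=1, keepdims=True)  # (3, T)
    u, _, _ = np.linalg.svd(c, full_matrices=False)
    lead = u[:, 0]
    proj = (np.eye(3) - np.outer(lead, lead)) @ c
    powers = [_band_peak_power(proj[i], trace.fps, band) for i in range(3)]
    return _finish(proj[int(np.argmax(powers))], trace.fps, band)


def ica_method(
    trace: RGBTrace,
    seed: int = 0,
    band: tuple[float, float] = DEFAULT_BAND,
    max_iter: int = 500,
) -> BVPWaveform:
    """Blind source separation of the detrended channels.

    Channels are linearly detrended and standardized, unmixed into three
    independent components by FastICA (negentropy maximization, seeded
    initialization), and the component with the strongest in-band spectral
    peak is kept.  If the unmixing does not converge the green channel is
    returned with a logged warning.
    """
    import warnings

    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    c = sp_signal.detrend(trace.values, axis=0)
    sd = c.std(axis=0)
    if np.any(sd == 0):
        log.warning("constant channel; falling back to green")
        return green(trace, band)
    c = (c - c.mean(axis=0)) / sd
    ica = FastICA(n_components=3, random_state=seed, max_iter=max_iter, whiten="unit-variance")
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            comps = ica.fit_transform(c)  # (T, 3)
        except ConvergenceWarning:
            log.warning("ICA failed to converge; falling back to green channel")
            return green(trace, band)
    powers = [_band_peak_power(comps[:, i], trace.fps, band) for i in range(3)]
    return _finish(comps[:, int(np.argmax(powers))], trace.fps, band)


BASELINES = {
    "green": green,
    "chrom": chrom,
    "pos": pos,
    "pbv": pbv,
    "lgi": lgi,
    "ica": ica_method,
}


def run_baseline(
    name: str,
    fs: FrameSequence,
    crop_fraction: float = 0.6,
    band: tuple[float, float] = DEFAULT_BAND,
    seed: int = 0,
) -> BVPWaveform:
    """Extract a pulse waveform from a frame sequence with a named method."""
    if name not in BASELINES:
        raise ValueError(f"unknown baseline {name!r}; choose from {sorted(BASELINES)}")
    trace = roi_trace(fs, crop_fraction)
    if name == "ica":
        return ica_method(trace, seed=seed, band=band)
    return BASELINES[name](trace, band=band)
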
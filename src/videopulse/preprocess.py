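"""Appearance/motion network inputs and fixed-length windowing.

The appearance stream averages adjacent frames and standardizes each frame
per channel; the motion stream differences adjacent frames and standardizes
likewise, cancelling common-mode intensity interference (ambient light,
global gain).  Windows default to 256 frames (~8.5 s at 30 fps), the unit
the network consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_media import FrameSequence

__all__ = [
    "ClipPair",
    "spatial_downsample",
    "appearance_input",
    "motion_input",
    "window_clips",
]

log = logging.getLogger(__name__)

ZERO_VARIANCE_EPS = 1e-6


@dataclass
class ClipPair:
    """Co-registered appearance and motion inputs for one window."""

    appearance: np.ndarray  # (T,H,W,3), per-frame standardized
    motion: np.ndarray  # (T,H,W,3), per-frame standardized
    fps: float
    window_index: int = 0

    def __post_init__(self):
        if self.appearance.shape != self.motion.shape:
            raise ValueError("appearance and motion shapes differ")
        if not (np.all(np.isfinite(self.appearance)) and np.all(np.isfinite(self.motion))):
            raise ValueError("non-finite values in clip")

    @property
    def n_frames(self) -> int:
        return self.appearance.shape[0]


def _area_average_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) matrix of exact box (area) averaging."""
    edges_out = np.linspace(0.0, n_in, n_out + 1)
    mat = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = edges_out[i], edges_out[i + 1]
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            overlap = min(hi, j + 1) - max(lo, j)
            if overlap > 0:
                mat[i, j] = overlap
    mat /= mat.sum(axis=1, keepdims=True)
    return mat


def spatial_downsample(fs: FrameSequence, size: int) -> FrameSequence:
    """Exact area (box) averaging of every frame to size x size; fps kept."""
    if size < 4:
        raise ValueError("size must be at least 4")
    t, h, w, _ = fs.frames.shape
    if h == size and w == size:
        return FrameSequence(fs.frames.copy(), fps=fs.fps, source_id=fs.source_id)
    a = _area_average_matrix(h, size)
    b = _area_average_matrix(w, size)
    out = np.einsum("ih,thwc,jw->tijc", a, fs.frames, b, optimize=True)
    return FrameSequence(np.clip(out, 0.0, 1.0), fps=fs.fps, source_id=fs.source_id)


def _standardize_frames(x: np.ndarray, eps: float) -> np.ndarray:
    """Per-frame, per-channel standard score with a zero-variance guard.

    Frames whose spatial standard deviation falls below `eps` are emitted
    as zeros: no variation means no signal, not a divide-by-zero.
    """
    mu = x.mean(axis=(1, 2), keepdims=True)
    sd = x.std(axis=(1, 2), keepdims=True)  # population form
    out = np.where(sd > eps, (x - mu) / np.where(sd > eps, sd, 1.0), 0.0)
    return out


def appearance_input(fs: FrameSequence, eps: float = ZERO_VARIANCE_EPS) -> np.ndarray:
    """Adjacent-frame average, then per-frame standard score.

    For t >= 1: Ave(t) = (C(t)+C(t-1))/2, A(t) = (Ave(t)-mu)/sigma computed
    per frame per channel.  A(0) duplicates A(1) so length matches input.
    """
    c = fs.frames
    ave = 0.5 * (c[1:] + c[:-1])
    a = _standardize_frames(ave, eps)
    return np.concatenate([a[:1], a], axis=0)


def motion_input(fs: FrameSequence, eps: float = ZERO_VARIANCE_EPS) -> np.ndarray:
    """Adjacent-frame difference, then per-frame standard score.

    For t >= 1: D(t) = C(t)-C(t-1), M(t) = (D(t)-mu)/sigma per frame per
    channel; M(0) is zero.  Static frame pairs emit zeros under the guard.
    """
    c = fs.frames
    d = c[1:] - c[:-1]
    m = _standardize_frames(d, eps)
    return np.concatenate([np.zeros_like(m[:1]), m], axis=0)


def window_clips(
    fs: FrameSequence,
    window: int = 256,
    stride: int | None = None,
    eps: float = ZERO_VARIANCE_EPS,
) -> list[ClipPair]:
    """Cut a sequence into fixed windows, each preprocessed independently.

    The trailing remainder shorter than `window` is dropped; an input
    shorter than one window yields an empty list with a logged warning.
    """
    stride = window if stride is None else stride
    if window < 2 or stride < 1:
        raise ValueError("window must be >= 2 and stride >= 1")
    t = fs.n_frames
    if t < window:
        log.warning("sequence of %d frames is shorter than window %d; no clips", t, window)
        return []
    clips = []
    for idx, start in enumerate(range(0, t - window + 1, stride)):
        sub = FrameSequence(fs.frames[start : start + window], fps=fs.fps,
                            source_id=fs.source_id)
        clips.append(
            ClipPair(
                appearance=appearance_input(sub, eps),
                motion=motion_input(sub, eps),
                fps=fs.fps,
                window_index=idx,
            )
        )
    return clips
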
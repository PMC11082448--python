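"""Frame-sequence and pulse-waveform containers with file ingestion.

Video input is either a directory of numbered PNG/JPEG frames
(lexicographic order) or any container the installed imageio plugins
decode.  Reference blood-volume-pulse (BVP) traces are plain text: one
amplitude per line, or two comma/whitespace-separated columns
(timestamp_seconds, amplitude).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FrameSequence",
    "BVPWaveform",
    "read_video",
    "write_frames",
    "read_reference_bvp",
    "write_waveform_csv",
    "resample_waveform",
]

_FRAME_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class FrameSequence:
    """Ordered RGB frames (T,H,W,3) with intensities in [0,1] and a frame rate."""

    frames: np.ndarray
    fps: float
    source_id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(f"frames must be (T,H,W,3), got {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("a frame sequence needs at least 2 frames")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("frame intensities must lie in [0,1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class BVPWaveform:
    """Uniformly sampled pulse waveform; role marks reference vs estimated."""

    samples: np.ndarray
    fps: float
    role: str = "estimated"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.samples.size < 2:
            raise ValueError("waveform needs at least 2 samples")
        if not self.fps > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fps}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite values")
        if self.role not in ("reference", "estimated"):
            raise ValueError(f"role must be 'reference' or 'estimated', got {self.role!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fps


def _to_unit(img: np.ndarray) -> np.ndarray:
    """Rescale integer pixel types by their type maximum; floats pass through."""
    arr = np.asarray(img)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def read_video(path: str | os.PathLike, fps: float | None = None) -> FrameSequence:
    """Read a frame directory or video container into a FrameSequence.

    For directories `fps` is required; for containers it overrides the
    container metadata when given.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file or directory: {p}")
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _FRAME_EXTS)
        if len(files) < 2:
            raise ValueError(f"{p} holds {len(files)} frames; at least 2 required")
        if fps is None or not fps > 0:
            raise ValueError("frame directories carry no time base; pass fps explicitly")
        frames = np.stack([_to_unit(iio.imread(f)) for f in files])
        return FrameSequence(frames, fps=float(fps), source_id=str(p))
    try:
        arr = iio.imread(p, index=None)
    except Exception as exc:  # codec missing / corrupt file
        raise IOError(f"cannot decode {p}: {exc}") from exc
    if fps is None:
        meta = iio.immeta(p)
        fps = meta.get("fps")
        if not fps or not fps > 0:
            raise ValueError(f"{p} has no usable fps metadata; pass fps explicitly")
    frames = _to_unit(np.asarray(arr))
    if frames.ndim == 3:  # single image
        raise ValueError(f"{p} decodes to a single frame; at least 2 required")
    return FrameSequence(frames, fps=float(fps), source_id=str(p))


def write_frames(fs: FrameSequence, out_dir: str | os.PathLike) -> Path:
    """Write frames as 8-bit PNGs frame_000000.png ...; lossless round trip
    up to the 8-bit quantization of the stored values."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(fs.frames):
        img = np.round(frame * 255.0).astype(np.uint8)
        iio.imwrite(out / f"frame_{i:06d}.png", img)
    return out


def read_reference_bvp(path: str | os.PathLike, fps: float | None = None) -> BVPWaveform:
    """Read a reference BVP trace.

    One column: amplitudes at `fps` (required).  Two columns: (timestamp_s,
    amplitude); fps inferred from mean timestamp spacing, irregular spacing
    linearly interpolated to a uniform grid.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file: {p}")
    rows: list[list[float]] = []
    with open(p) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if lineno == 1 and any(not _is_number(tok) for tok in parts):
                continue  # header row
            try:
                rows.append([float(tok) for tok in parts])
            except ValueError as exc:
                raise ValueError(f"{p}:{lineno}: non-numeric row {line!r}") from exc
    if not rows:
        raise ValueError(f"{p} contains no samples")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError(f"{p}: inconsistent column count")
    arr = np.asarray(rows, dtype=np.float64)
    if ncol == 1:
        if fps is None or not fps > 0:
            raise ValueError("single-column trace needs an explicit fps")
        return BVPWaveform(arr[:, 0], fps=float(fps), role="reference")
    ts, vals = arr[:, 0], arr[:, 1]
    if np.any(np.diff(ts) <= 0):
        raise ValueError(f"{p}: timestamps must be strictly increasing")
    inferred = (len(ts) - 1) / (ts[-1] - ts[0])
    fps = float(fps) if fps else float(inferred)
    grid = np.arange(len(ts)) / fps + ts[0]
    uniform = np.interp(np.clip(grid, ts[0], ts[-1]), ts, vals)
    return BVPWaveform(uniform, fps=fps, role="reference")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_waveform_csv(w: BVPWaveform, path: str | os.PathLike) -> Path:
    """Two-column CSV (time_s, amplitude)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([w.times, w.samples])
    header = "time_s,amplitude"
    np.savetxt(p, data, delimiter=",", header=header, comments="", fmt="%.10g")
    return p


def resample_waveform(w: BVPWaveform, target_fps: float) -> BVPWaveform:
    """Linear interpolation onto a uniform grid at target_fps over the same
    duration; endpoints clamped; role preserved."""
    if not target_fps > 0:
        raise ValueError("target_fps must be positive")
    if target_fps == w.fps:
        return replace(w, samples=w.samples.copy())
    # grid spans [0, (N-1)/fps]; the last in-range target sample is kept
    n_out = int(np.floor((w.n_samples - 1) / w.fps * target_fps + 1e-9)) + 1
    t_out = np.arange(n_out) / target_fps
    out = np.interp(np.clip(t_out, 0, w.times[-1]), w.times, w.samples)
    return BVPWaveform(out, fps=float(target_fps), role=w.role)
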
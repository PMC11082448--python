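"""Desk-scale synthetic benchmark: the standard end-to-end experiment.

Generates a seeded corpus of pulse-modulated clips (heart rates drawn from
50–110 bpm at the generator's default noise conditions), trains a network
variant on it, and scores held-out clips with the package's waveform and
heart-rate metrics.  The problem sizes here — 8x8 input after area
downsampling, 8/12 feature channels, 24 training and 12 held-out windows of
256 frames, 20 epochs — are deliberately small so a full
train-evaluate-compare cycle runs in well under a minute per model on one
CPU core; they are the package's reference conditions for self-validation,
not a claim about full-scale datasets.
"""

from __future__ import annotations

import numpy as np

from .io_media import BVPWaveform
from .metrics import hr_metrics, limits_of_agreement, pearson_r, snr_time
from .model import ModelConfig, PulseNet, build_model, train_model
from .preprocess import ClipPair, spatial_downsample, window_clips
from .pulse_rate import estimate_hr
from .synthgen import make_dataset

__all__ = [
    "DESK_INPUT_SIZE",
    "desk_model_config",
    "make_benchmark",
    "prepare_clips",
    "train_desk_model",
    "evaluate_model",
    "DESK_TRAIN_KW",
]

DESK_INPUT_SIZE = 8
DESK_HR_RANGE = (50.0, 110.0)
DESK_N_TRAIN = 24
DESK_N_TEST = 12
DESK_TRAIN_KW = dict(lr=3e-3, epochs=20, batch_size=4)


def desk_model_config(variant: str = "fm-fcn", seed: int = 0) -> ModelConfig:
    """Desk-scale model: 8x8 input, 8/12 channels, light dropout."""
    return ModelConfig(
        variant=variant,
        input_size=DESK_INPUT_SIZE,
        window=256,
        conv_channels=(8, 12),
        dropout_rates=(0.1, 0.1, 0.2),
        head_hidden=32,
        seed=seed,
    )


def prepare_clips(
    raw: list, size: int = DESK_INPUT_SIZE, window: int = 256
) -> list[tuple[ClipPair, BVPWaveform]]:
    """Downsample rendered clips and pair each first window with its truth."""
    out = []
    for fs, ref in raw:
        clip = window_clips(spatial_downsample(fs, size), window=window)[0]
        out.append(
            (clip, BVPWaveform(ref.samples[:window], fps=ref.fps, role="reference"))
        )
    return out


def make_benchmark(
    seed: int = 0,
    n_train: int = DESK_N_TRAIN,
    n_test: int = DESK_N_TEST,
    hr_range: tuple[float, float] = DESK_HR_RANGE,
    size: int = DESK_INPUT_SIZE,
):
    """(train, test) lists of (ClipPair, reference BVPWaveform)."""
    train_raw = make_dataset(n_train, {"hr_bpm": hr_range}, seed=seed * 7919 + 100)
    test_raw = make_dataset(n_test, {"hr_bpm": hr_range}, seed=seed * 7919 + 200)
    return prepare_clips(train_raw, size), prepare_clips(test_raw, size)


def train_desk_model(
    variant: str,
    train: list[tuple[ClipPair, BVPWaveform]],
    seed: int = 0,
    **train_kw,
) -> tuple[PulseNet, list[dict]]:
    kw = {**DESK_TRAIN_KW, **train_kw}
    net = build_model(desk_model_config(variant, seed=seed))
    history = train_model(net, train, seed=seed, **kw)
    return net, history


def evaluate_model(
    net: PulseNet, test: list[tuple[ClipPair, BVPWaveform]]
) -> dict:
    """Score a model on held-out windows.

    Returns scalar summaries plus the per-window estimated/reference heart
    rates and absolute errors used by the pairwise model-comparison test.
    """
    snrs, rs, e_hr, r_hr = [], [], [], []
    for clip, ref in test:
        est = net(clip)
        s = est.samples
        sd = s.std()
        s = (s - s.mean()) / (sd if sd > 0 else 1.0)
        snrs.append(snr_time(ref.samples, s))
        rs.append(pearson_r(ref.samples, s) if sd > 0 else 0.0)
        r_hr.append(estimate_hr(ref).bpm)
        if sd > 0:
            e_hr.append(estimate_hr(est).bpm)
        else:  # flat output counts as a maximal miss
            e_hr.append(0.0)
    e_hr, r_hr = np.asarray(e_hr), np.asarray(r_hr)
    hmae, hmre, hsd, hrr, hacc = hr_metrics(e_hr, r_hr)
    lo, up, _ = limits_of_agreement(e_hr, r_hr)
    return {
        "bvp_snr_db": float(np.mean(snrs)),
        "bvp_r": float(np.mean(rs)),
        "hr_mae": hmae,
        "hr_mre_percent": hmre,
        "hr_sd": hsd,
        "hr_acc": hacc,
        "loa": (lo, up),
        "e_hr": e_hr,
        "r_hr": r_hr,
        "hr_abs_err": np.abs(e_hr - r_hr),
        "n_windows": len(test),
    }
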
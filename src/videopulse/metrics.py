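"""Evaluation framework: waveform quality, heart-rate accuracy, agreement.

Waveform metrics (MAE, Pearson R, time-domain SNR) are computed on
per-window standardized pairs — the estimated pulse has arbitrary units, so
a common scale is fixed first.  Heart-rate metrics follow the clinical
tolerance of ±10% of reference or ±5 bpm, whichever is greater
(ANSI/AAMI EC13), and agreement is summarized by Bland–Altman limits
mean ± 1.96 SD.  Standard deviations use the population form throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .io_media import BVPWaveform
from .pulse_rate import DEFAULT_BAND, estimate_hr

__all__ = [
    "MetricsReport",
    "ComparisonResult",
    "mae",
    "pearson_r",
    "snr_time",
    "hr_metrics",
    "limits_of_agreement",
    "paired_ttest",
    "evaluate",
    "bland_altman_plot",
    "SNR_CAP_DB",
]

SNR_CAP_DB = 80.0


@dataclass
class MetricsReport:
    bvp_mae: float
    bvp_r: float
    bvp_snr_db: float
    hr_mae: float
    hr_mre_percent: float
    hr_sd: float
    hr_r: float
    hr_acc: float
    loa_lower: float
    loa_upper: float
    n_windows: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComparisonResult:
    h: int
    p: float
    ci: tuple[float, float]
    alpha: float = 0.05


def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error (1/N) sum |yhat_i - y_i|."""
    y, yhat = _pair(y, yhat)
    if y.size < 1:
        raise ValueError("need at least one sample")
    return float(np.mean(np.abs(yhat - y)))


def pearson_r(y, yhat) -> float:
    """Product-moment correlation, clamped to [-1, 1] against rounding."""
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least two samples")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("correlation undefined for a constant input")
    n = y.size
    num = n * np.sum(y * yhat) - np.sum(y) * np.sum(yhat)
    den = np.sqrt(n * np.sum(y**2) - np.sum(y) ** 2) * np.sqrt(
        n * np.sum(yhat**2) - np.sum(yhat) ** 2
    )
    return float(np.clip(num / den, -1.0, 1.0))


def snr_time(y, yhat, cap_db: float = SNR_CAP_DB) -> float:
    """Time-domain SNR: 10 log10( sum y_i^2 / sum (y_i - yhat_i)^2 ) dB.

    The reference carries the signal energy; the residual to the estimate is
    the noise.  A zero-residual pair returns `cap_db` instead of infinity.
    """
    y, yhat = _pair(y, yhat)
    sig = float(np.sum(y**2))
    if sig <= 0:
        raise ValueError("reference has no energy; SNR undefined")
    noise = float(np.sum((y - yhat) ** 2))
    if noise == 0:
        return cap_db
    return float(min(10.0 * np.log10(sig / noise), cap_db))


def hr_tolerance(r_hr: np.ndarray) -> np.ndarray:
    """Allowable absolute error: max(5 bpm, 10% of reference)."""
    return np.maximum(5.0, 0.10 * np.asarray(r_hr, dtype=np.float64))


def hr_metrics(e_hr, r_hr) -> tuple[float, float, float, float, float]:
    """(MAE, MRE %, error SD, Pearson R, ACC) of paired heart rates.

    MRE is the mean of |e-r|/r in percent; SD is the population standard
    deviation of the absolute errors; ACC the fraction of windows whose
    error is within the clinical tolerance (boundary inclusive).  R is NaN
    when either series is constant (single-window reports).
    """
    r, e = _pair(r_hr, e_hr)
    if r.size < 1:
        raise ValueError("need at least one paired rate")
    if np.any(r <= 0):
        raise ValueError("reference heart rates must be positive")
    err = np.abs(e - r)
    m = float(err.mean())
    mre = float(np.mean(err / r) * 100.0)
    sd = float(np.sqrt(np.mean((err - err.mean()) ** 2)))  # population form
    try:
        rr = pearson_r(r, e)
    except ValueError:
        rr = float("nan")
    within = err <= hr_tolerance(r)
    acc = float(np.mean(within))
    return m, mre, sd, rr, acc


def limits_of_agreement(e_hr, r_hr) -> tuple[float, float, float]:
    """Bland–Altman 95% limits on signed differences d = e - r.

    Returns (lower, upper, mean_diff) with limits mean ± 1.96 SD
    (population SD, consistent with the error-SD metric).
    """
    r, e = _pair(r_hr, e_hr)
    if r.size < 2:
        raise ValueError("need at least two pairs for limits of agreement")
    d = e - r
    mu = float(d.mean())
    sd = float(np.sqrt(np.mean((d - mu) ** 2)))
    return mu - 1.96 * sd, mu + 1.96 * sd, mu


def paired_ttest(err_a, err_b, alpha: float = 0.05) -> ComparisonResult:
    """Two-sided paired t-test on aligned error series.

    Returns the significance flag h (1 iff p < alpha), the p-value, and the
    (1-alpha) confidence interval of the mean difference a - b.  A
    degenerate all-zero difference yields p = 1, h = 0.
    """
    a, b = _pair(err_a, err_b)
    if a.size < 2:
        raise ValueError("need at least two paired errors")
    d = a - b
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return ComparisonResult(h=0, p=1.0, ci=(0.0, 0.0), alpha=alpha)
        return ComparisonResult(h=1, p=0.0, ci=(mean, mean), alpha=alpha)
    t_res = stats.ttest_rel(a, b)
    p = float(t_res.pvalue)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    half = tcrit * sd / np.sqrt(n)
    return ComparisonResult(h=int(p < alpha), p=p, ci=(mean - half, mean + half),
                            alpha=alpha)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def evaluate(
    e_bvp: BVPWaveform,
    r_bvp: BVPWaveform,
    band: tuple[float, float] = DEFAULT_BAND,
    window: int = 256,
    zero_pad_factor: int = 4,
) -> MetricsReport:
    """Full report over per-window pairs of estimated vs reference pulse.

    Both waveforms must share a sampling rate (resample first) and cover at
    least one window.  Waveform metrics are computed per standardized
    window then averaged; heart rates are estimated per window for both
    signals with the same spectral machinery.
    """
    if e_bvp.fps != r_bvp.fps:
        raise ValueError("sampling rates differ; resample before evaluating")
    n = min(e_bvp.n_samples, r_bvp.n_samples)
    if abs(e_bvp.n_samples - r_bvp.n_samples) > 1:
        raise ValueError("waveform durations differ by more than one sample")
    if n < window:
        raise ValueError(f"need at least one window of {window} samples, got {n}")
    maes, rs, snrs, ehr, rhr = [], [], [], [], []
    for start in range(0, n - window + 1, window):
        e = _standardize(e_bvp.samples[start : start + window])
        r = _standardize(r_bvp.samples[start : start + window])
        maes.append(mae(r, e))
        try:
            rs.append(pearson_r(r, e))
        except ValueError:
            rs.append(0.0)
        snrs.append(snr_time(r, e))
        if e.std() > 0:
            ehr.append(estimate_hr(BVPWaveform(e, fps=e_bvp.fps), band=band,
                                   zero_pad_factor=zero_pad_factor).bpm)
        else:
            ehr.append(float("nan"))
        rhr.append(estimate_hr(BVPWaveform(r, fps=r_bvp.fps), band=band,
                               zero_pad_factor=zero_pad_factor).bpm)
    ehr = np.asarray(ehr)
    rhr = np.asarray(rhr)
    ok = np.isfinite(ehr)
    if not np.all(ok):  # flat estimate windows count as maximal misses
        ehr = np.where(ok, ehr, band[1] * 60.0)
    hmae, hmre, hsd, hrr, hacc = hr_metrics(ehr, rhr)
    if len(rhr) >= 2:
        lo, up, _ = limits_of_agreement(ehr, rhr)
    else:
        lo = up = float(ehr[0] - rhr[0])
    return MetricsReport(
        bvp_mae=float(np.mean(maes)),
        bvp_r=float(np.mean(rs)),
        bvp_snr_db=float(np.mean(snrs)),
        hr_mae=hmae,
        hr_mre_percent=hmre,
        hr_sd=hsd,
        hr_r=hrr,
        hr_acc=hacc,
        loa_lower=lo,
        loa_upper=up,
        n_windows=len(maes),
    )


def bland_altman_plot(e_hr, r_hr, ax=None, title: str | None = None):
    """Difference-vs-mean scatter with dashed limits of agreement."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    r, e = _pair(r_hr, e_hr)
    lo, up, mu = limits_of_agreement(e, r)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((e + r) / 2.0, e - r, s=14, alpha=0.7)
    for yv, style in ((mu, "-"), (lo, "--"), (up, "--")):
        ax.axhline(yv, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of estimated and reference HR (bpm)")
    ax.set_ylabel("estimated - reference HR (bpm)")
    if title:
        ax.set_title(title)
    return ax
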
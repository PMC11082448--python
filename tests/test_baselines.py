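"""Classical pulse extractors: recovery, invariances, suppression properties."""

import numpy as np
import pytest

import videopulse as vp
from videopulse.baselines import (
    DEFAULT_PBV_SIGNATURE,
    RGBTrace,
    chrom,
    green,
    ica_method,
    lgi,
    pbv,
    pos,
    roi_trace,
)

FPS = 30.0


def _trace(values):
    return RGBTrace(np.asarray(values, dtype=np.float64), fps=FPS)


def _tone(freq, n=600, amp=1.0, phase=0.0):
    t = np.arange(n) / FPS
    return amp * np.sin(2 * np.pi * freq * t + phase)


def _band_power_ratio(x, f_num, f_den):
    """Spectral power at f_num relative to f_den (padded FFT)."""
    spec = np.abs(np.fft.rfft(x - x.mean(), n=8 * len(x))) ** 2
    freqs = np.fft.rfftfreq(8 * len(x), d=1.0 / FPS)
    p = lambda f: spec[np.argmin(np.abs(freqs - f))]
    return p(f_num) / p(f_den)


class TestROITrace:
    def test_constant_video(self):
        fs = vp.FrameSequence(np.full((3, 8, 8, 3), 0.5), fps=FPS)
        tr = roi_trace(fs, 0.6)
        np.testing.assert_allclose(tr.values, 0.5)

    def test_full_crop_equals_frame_mean(self, rng):
        frames = rng.random((4, 9, 9, 3))
        fs = vp.FrameSequence(frames, fps=FPS)
        tr = roi_trace(fs, 1.0)
        np.testing.assert_allclose(tr.values, frames.mean(axis=(1, 2)))

    def test_pulse_amplitude_scales_with_skin_coverage(self, clean_clip):
        fs, ref = clean_clip
        cfg_amp, gain_g = 0.01, 1.0
        tr = roi_trace(fs, 1.0)
        g = tr.values[:, 1]
        skin_frac = 0.5  # generator default: ellipse covers half the frame
        expected_ptp = cfg_amp * gain_g * np.ptp(ref.samples) * skin_frac
        assert np.ptp(g) == pytest.approx(expected_ptp, rel=0.05)


class TestGreen:
    def test_recovers_green_sinusoid(self):
        vals = np.column_stack([np.full(600, 0.5), 0.5 + 0.01 * _tone(1.2),
                                np.full(600, 0.5)])
        out = green(_trace(vals))
        r = np.corrcoef(out.samples[50:-50], _tone(1.2)[50:-50])[0, 1]
        assert abs(r) > 0.99

    def test_constant_trace_zero_output(self):
        out = green(_trace(np.full((100, 3), 0.4)))
        np.testing.assert_array_equal(out.samples, 0.0)

    def test_affine_invariance(self):
        vals = np.column_stack([np.full(600, 0.5), 0.5 + 0.01 * _tone(1.2),
                                np.full(600, 0.5)])
        a = green(_trace(vals)).samples
        vals2 = vals.copy()
        vals2[:, 1] = 0.3 * vals2[:, 1] + 0.2
        b = green(_trace(vals2)).samples
        np.testing.assert_allclose(a, b, atol=1e-8)


def _flicker_plus_pulse(flicker_amp=0.05, pulse_amp=0.005, n=900):
    """Achromatic flicker at 1.0 Hz plus a blood-volume-like pulse at 1.8 Hz."""
    base = np.full((n, 3), 0.5)
    base += flicker_amp * _tone(1.0, n)[:, None]  # equal in all channels
    pv = np.asarray(DEFAULT_PBV_SIGNATURE)
    base += pulse_amp * np.outer(_tone(1.8, n), pv)
    return _trace(base)


@pytest.mark.parametrize("method", [chrom, pos])
def test_chrominance_methods_suppress_achromatic_flicker(method):
    tr = _flicker_plus_pulse()
    out = method(tr).samples
    # flicker-to-pulse power ratio, compared with the raw green channel
    ratio_out = _band_power_ratio(out, 1.0, 1.8)
    ratio_in = _band_power_ratio(tr.values[:, 1], 1.0, 1.8)
    assert 10 * np.log10(ratio_in / ratio_out) >= 20.0


def test_chrom_white_balance_invariance():
    tr = _flicker_plus_pulse()
    gains = np.array([1.3, 0.8, 1.1])
    out_a = chrom(tr).samples
    out_b = chrom(_trace(tr.values * gains)).samples
    assert abs(np.corrcoef(out_a, out_b)[0, 1]) > 0.999


def test_pos_single_window_degenerate_case():
    n = 64
    rng = np.random.default_rng(0)
    vals = 0.5 + 0.01 * rng.normal(size=(n, 3))
    tr = RGBTrace(vals, fps=FPS)
    out = pos(tr, win_seconds=n / FPS + 10)  # window spans the whole trace
    # direct single-window computation
    mean = vals.mean(axis=0)
    rn, gn, bn = (vals / mean).T
    s1, s2 = gn - bn, gn + bn - 2 * rn
    h = s1 + (s1.std() / s2.std()) * s2
    from videopulse.baselines import _finish

    expected = _finish(h - h.mean(), FPS, (0.66, 3.0)).samples
    np.testing.assert_allclose(out.samples, expected, atol=1e-10)


class TestPBV:
    def test_recovers_variation_along_signature(self):
        tr_vals = 0.5 + 0.01 * np.outer(_tone(1.5), DEFAULT_PBV_SIGNATURE)
        out = pbv(_trace(tr_vals))
        r = np.corrcoef(out.samples[50:-50], _tone(1.5)[50:-50])[0, 1]
        assert abs(r) > 0.99

    def test_orthogonal_variation_suppressed(self):
        pv = np.asarray(DEFAULT_PBV_SIGNATURE)
        ortho = np.array([pv[1], -pv[0], 0.0])
        mixed = 0.5 + 0.02 * np.outer(_tone(1.0), ortho) \
            + 0.004 * np.outer(_tone(1.8), pv)
        out = pbv(_trace(mixed)).samples
        assert _band_power_ratio(out, 1.8, 1.0) > 10.0  # pulse dominates

    def test_ridge_insensitive_when_well_conditioned(self, rng):
        vals = 0.5 + 0.01 * rng.normal(size=(300, 3))
        a = pbv(_trace(vals), ridge=0.0).samples
        b = pbv(_trace(vals), ridge=1e-9).samples
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestLGI:
    def test_dominant_direction_is_removed(self):
        # the big rank-1 component at 1.2 Hz is projected out, so the tiny
        # secondary component at 2.0 Hz dominates the output
        vals = (0.5 + 0.02 * np.outer(_tone(1.2, 900), [1.0, 0.8, 0.6])
                + 1e-4 * np.outer(_tone(2.0, 900), [0.2, 1.0, -0.5]))
        out = lgi(_trace(vals)).samples
        assert _band_power_ratio(out, 2.0, 1.2) > 10.0

    def test_recovers_pulse_under_common_mode_drift(self, default_clip):
        fs, ref = default_clip
        out = vp.run_baseline("lgi", fs, crop_fraction=1.0)
        err = abs(vp.estimate_hr(out).bpm - vp.estimate_hr(ref).bpm)
        assert err <= 60 * FPS / (fs.n_frames * 4)

    def test_invariant_to_rotated_drift_direction(self):
        pv = np.asarray(DEFAULT_PBV_SIGNATURE)
        pulse = 0.004 * np.outer(_tone(1.8, n=900), pv)
        for drift_dir in ([1.0, 1.0, 1.0], [1.0, 0.9, 1.2]):
            vals = 0.5 + 0.05 * np.outer(_tone(0.2, n=900), drift_dir) + pulse
            out = lgi(_trace(vals))
            hr = vp.estimate_hr(out).bpm
            assert hr == pytest.approx(1.8 * 60, abs=2.0)


class TestICA:
    def test_separates_a_source_from_a_random_mixture(self, rng):
        # identifiability: the selected component matches one pure source,
        # not a mixture, up to sign
        n = 900
        srcs = np.column_stack([_tone(0.8, n), _tone(1.5, n, phase=1.0),
                                _tone(2.4, n, phase=2.0)])
        mix = rng.uniform(0.2, 1.0, size=(3, 3)) + np.eye(3)
        tr = RGBTrace(0.5 + 0.01 * srcs @ mix.T, fps=FPS)
        out = ica_method(tr, seed=0, band=(0.5, 3.0)).samples
        cors = [abs(np.corrcoef(out[50:-50], srcs[50:-50, k])[0, 1]) for k in range(3)]
        assert max(cors) > 0.95

    def test_seeded_determinism(self, default_clip):
        fs, _ = default_clip
        tr = roi_trace(fs, 1.0)
        a = ica_method(tr, seed=3).samples
        b = ica_method(tr, seed=3).samples
        np.testing.assert_array_equal(a, b)

    def test_recovers_default_clip_hr(self, default_clip):
        fs, ref = default_clip
        out = vp.run_baseline("ica", fs, crop_fraction=1.0, seed=0)
        err = abs(vp.estimate_hr(out).bpm - vp.estimate_hr(ref).bpm)
        assert err <= 60 * FPS / (fs.n_frames * 4)


@pytest.mark.parametrize("name", sorted(vp.BASELINES))
def test_every_baseline_is_gain_invariant(name, default_clip):
    fs, _ = default_clip
    tr = roi_trace(fs, 1.0)
    kw = {"seed": 0} if name == "ica" else {}
    a = vp.BASELINES[name](tr, **kw).samples
    scaled = RGBTrace(np.clip(tr.values * 1.7, 0, None), fps=tr.fps)
    b = vp.BASELINES[name](scaled, **kw).samples
    assert abs(np.corrcoef(a, b)[0, 1]) > 0.999


def test_unknown_baseline_name_errors(clean_clip):
    with pytest.raises(ValueError, match="unknown baseline"):
        vp.run_baseline("magic", clean_clip[0])
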
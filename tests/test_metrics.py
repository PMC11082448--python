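"""Waveform/heart-rate metrics, agreement limits and model comparison."""

import math

import numpy as np
import pytest

import videopulse as vp
from videopulse.metrics import SNR_CAP_DB, hr_tolerance, snr_time


# -- independent naive-loop oracles (plain Python, no numpy vectorization) --

def naive_mae(y, yhat):
    return sum(abs(b - a) for a, b in zip(y, yhat)) / len(y)


def naive_pearson(y, yhat):
    n = len(y)
    sy, syh = sum(y), sum(yhat)
    num = n * sum(a * b for a, b in zip(y, yhat)) - sy * syh
    den = math.sqrt(n * sum(a * a for a in y) - sy**2) * math.sqrt(
        n * sum(b * b for b in yhat) - syh**2
    )
    return num / den


def naive_snr(y, yhat):
    return 10 * math.log10(sum(a * a for a in y) / sum((a - b) ** 2 for a, b in zip(y, yhat)))


def naive_hr_metrics(e, r):
    n = len(r)
    err = [abs(a - b) for a, b in zip(e, r)]
    m = sum(err) / n
    mre = 100.0 * sum(abs(a - b) / b for a, b in zip(e, r)) / n
    mu = sum(err) / n
    sd = math.sqrt(sum((x - mu) ** 2 for x in err) / n)
    ate = sum(1 for a, b in zip(e, r) if abs(a - b) <= max(5.0, 0.10 * b))
    return m, mre, sd, ate / n


def naive_loa(e, r):
    d = [a - b for a, b in zip(e, r)]
    mu = sum(d) / len(d)
    sd = math.sqrt(sum((x - mu) ** 2 for x in d) / len(d))
    return mu - 1.96 * sd, mu + 1.96 * sd


class TestMAE:
    def test_identical_series_zero(self):
        assert vp.mae([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_case(self):
        assert vp.mae([1, 2, 3], [2, 4, 2]) == pytest.approx(4 / 3)

    def test_symmetry(self, rng):
        y, yh = rng.normal(size=(2, 30))
        assert vp.mae(y, yh) == vp.mae(yh, y)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            vp.mae([1.0], [1.0, 2.0])


class TestPearsonR:
    def test_positive_affine_is_one(self, rng):
        y = rng.normal(size=50)
        assert vp.pearson_r(y, 2 * y + 1) == pytest.approx(1.0)

    def test_negation_is_minus_one(self, rng):
        y = rng.normal(size=50)
        assert vp.pearson_r(y, -y) == pytest.approx(-1.0)

    def test_hand_case_matches_printed_formula(self):
        got = vp.pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert got == pytest.approx(naive_pearson([1, 2, 3, 4], [1, 3, 2, 4]), abs=1e-12)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            vp.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSNR:
    @pytest.mark.parametrize(
        "y, yhat, expected",
        [
            ([1, 1, 1, 1], [0, 0, 0, 0], 0.0),
            ([2, 2], [1, 1], 10 * math.log10(8 / 2)),
        ],
    )
    def test_hand_cases(self, y, yhat, expected):
        assert snr_time(y, yhat) == pytest.approx(expected, abs=1e-10)

    def test_zero_error_is_capped(self):
        assert snr_time([1.0, 2.0], [1.0, 2.0]) == SNR_CAP_DB

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError, match="energy"):
            snr_time([0.0, 0.0], [1.0, 1.0])


class TestHRMetrics:
    def test_perfect_estimates(self):
        m, mre, sd, r, acc = vp.hr_metrics([60.0, 80.0], [60.0, 80.0])
        assert (m, mre, sd, acc) == (0.0, 0.0, 0.0, 1.0)

    def test_clinical_tolerance_rule(self):
        # 60->64: tol max(5, 6)=6 covers the 4 bpm error; 40->46: tol 5 < 6
        assert hr_tolerance(np.array([60.0]))[0] == 6.0
        _, _, _, _, acc = vp.hr_metrics([64.0, 46.0, 90.0], [60.0, 40.0, 90.0])
        assert acc == pytest.approx(2 / 3)

    def test_error_sd_population_form(self):
        # err=[0,2] -> mean 1, SD sqrt(((0-1)^2+(2-1)^2)/2) = 1
        _, _, sd, _, _ = vp.hr_metrics([60.0, 62.0], [60.0, 60.0])
        assert sd == pytest.approx(1.0)

    def test_nonpositive_reference_errors(self):
        with pytest.raises(ValueError, match="positive"):
            vp.hr_metrics([60.0], [0.0])

    def test_acc_monotone_as_errors_grow(self, rng):
        r = rng.uniform(50, 110, size=40)
        accs = []
        for scale in (0.0, 3.0, 8.0, 20.0):
            e = r + scale * np.sign(rng.normal(size=40))
            accs.append(vp.hr_metrics(e, r)[4])
        assert all(a >= b for a, b in zip(accs, accs[1:]))


class TestLimitsOfAgreement:
    def test_symmetric_pair(self):
        lo, up, mu = vp.limits_of_agreement([59.0, 61.0], [60.0, 60.0])
        assert (lo, up, mu) == pytest.approx((-1.96, 1.96, 0.0))

    def test_perfect_agreement_is_degenerate(self):
        lo, up, _ = vp.limits_of_agreement([60.0, 80.0], [60.0, 80.0])
        assert lo == up == 0.0

    def test_translation_equivariance(self, rng):
        e = rng.uniform(50, 110, size=30)
        r = rng.uniform(50, 110, size=30)
        lo, up, _ = vp.limits_of_agreement(e, r)
        lo2, up2, _ = vp.limits_of_agreement(e + 7.0, r)
        assert (lo2, up2) == pytest.approx((lo + 7.0, up + 7.0))

    def test_width_equals_2x196_sd(self, rng):
        e = rng.normal(size=50)
        r = rng.normal(size=50)
        lo, up, _ = vp.limits_of_agreement(e, r)
        d = e - r
        assert up - lo == pytest.approx(2 * 1.96 * d.std())


class TestMetricOraclesOnRandomVectors:
    def test_all_match_naive_loops(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 100))
            y = list(rng.normal(size=n))
            yh = list(rng.normal(size=n))
            assert vp.mae(y, yh) == pytest.approx(naive_mae(y, yh), abs=1e-10)
            assert snr_time(y, yh) == pytest.approx(naive_snr(y, yh), abs=1e-10)
            if np.std(y) > 0 and np.std(yh) > 0:
                assert vp.pearson_r(y, yh) == pytest.approx(naive_pearson(y, yh), abs=1e-10)
            e = list(rng.uniform(40, 180, size=n))
            r = list(rng.uniform(40, 180, size=n))
            m, mre, sd, _, acc = vp.hr_metrics(e, r)
            nm, nmre, nsd, nacc = naive_hr_metrics(e, r)
            assert (m, mre, sd, acc) == pytest.approx((nm, nmre, nsd, nacc), abs=1e-10)
            lo, up, _ = vp.limits_of_agreement(e, r)
            assert (lo, up) == pytest.approx(naive_loa(e, r), abs=1e-10)


class TestPairedTTest:
    def test_identical_series_not_significant(self):
        res = vp.paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.h, res.p) == (0, 1.0)

    def test_constant_shift_detected_at_large_n(self, rng):
        b = rng.normal(size=200)
        a = b + 1.0 + rng.normal(scale=0.5, size=200)
        res = vp.paired_ttest(a, b)
        assert res.h == 1 and res.ci[0] > 0

    def test_swapping_negates_ci_and_keeps_p(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        r1 = vp.paired_ttest(a, b)
        r2 = vp.paired_ttest(b, a)
        assert r1.p == pytest.approx(r2.p)
        assert r1.ci == pytest.approx((-r2.ci[1], -r2.ci[0]))

    def test_ci_matches_t_distribution(self, rng):
        from scipy import stats

        a = rng.normal(size=25)
        b = rng.normal(size=25)
        res = vp.paired_ttest(a, b, alpha=0.05)
        d = a - b
        lo, hi = stats.t.interval(0.95, 24, loc=d.mean(), scale=d.std(ddof=1) / 5)
        assert res.ci == pytest.approx((lo, hi))

    def test_alpha_one_flags_everything(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        assert vp.paired_ttest(a, b, alpha=1.0).h == 1


class TestEvaluate:
    def _wave(self, samples, fps=30.0):
        return vp.BVPWaveform(samples, fps=fps)

    def test_perfect_estimator(self):
        t = np.arange(512) / 30.0
        y = np.sin(2 * np.pi * 1.2 * t)
        rep = vp.evaluate(self._wave(y), self._wave(y))
        assert rep.bvp_mae == 0.0
        assert rep.bvp_r == 1.0
        assert rep.bvp_snr_db == SNR_CAP_DB
        assert rep.hr_acc == 1.0
        assert (rep.loa_lower, rep.loa_upper) == (0.0, 0.0)
        assert rep.n_windows == 2

    def test_noise_estimator_scores_poorly(self, rng):
        n = 20 * 256
        t = np.arange(n) / 30.0
        ref = np.sin(2 * np.pi * 1.2 * t)
        noise = rng.normal(size=n)
        rep = vp.evaluate(self._wave(noise), self._wave(ref))
        assert rep.hr_acc < 0.5
        assert abs(rep.bvp_r) < 0.2

    def test_report_matches_component_calls(self, rng):
        n = 512
        ref = np.sin(2 * np.pi * 1.5 * np.arange(n) / 30.0)
        est = ref + 0.3 * rng.normal(size=n)
        rep = vp.evaluate(self._wave(est), self._wave(ref))
        maes, rs = [], []
        for s in (0, 256):
            e = est[s : s + 256]
            r = ref[s : s + 256]
            e = (e - e.mean()) / e.std()
            r = (r - r.mean()) / r.std()
            maes.append(vp.mae(r, e))
            rs.append(vp.pearson_r(r, e))
        assert rep.bvp_mae == pytest.approx(np.mean(maes))
        assert rep.bvp_r == pytest.approx(np.mean(rs))

    def test_mismatched_rates_error(self):
        a = self._wave(np.ones(300))
        b = vp.BVPWaveform(np.ones(300), fps=25.0)
        with pytest.raises(ValueError, match="rates"):
            vp.evaluate(a, b)

    def test_too_short_errors(self):
        a = self._wave(np.sin(np.arange(100)))
        with pytest.raises(ValueError, match="window"):
            vp.evaluate(a, a)
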
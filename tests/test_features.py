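"""Zero crossings, pair segments, sum-of-sines fits and the eight features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pronosup.errors import FeatureError, InputError, OscillationError
from pronosup.features import (FEATURE_NAMES, build_pair_segments,
                               compute_features, fit_sum_of_sines,
                               register_feature, rotation_angle, zero_crossings)


class TestZeroCrossings:
    def test_analytic_sine_roots(self):
        t = np.arange(0, 2, 0.01)
        c = zero_crossings(np.sin(2 * np.pi * t), t)
        np.testing.assert_allclose(c, [0.5, 1.0, 1.5], atol=1 / 200)

    def test_strictly_positive_signal_rejected(self):
        t = np.arange(0, 2, 0.01)
        with pytest.raises(OscillationError):
            zero_crossings(np.sin(2 * np.pi * t) + 2.0, t)

    def test_small_noise_does_not_change_count(self):
        t = np.arange(0, 4, 0.01)
        y = np.sin(2 * np.pi * 1.5 * t)
        rng = np.random.default_rng(1)
        noisy = y + rng.normal(0, 0.01, y.size)
        assert zero_crossings(noisy, t).size == zero_crossings(y, t).size


class TestPairSegments:
    def test_ten_oscillations_give_nine_segments(self):
        c = np.arange(11) * 0.5  # 11 crossings = 10 oscillations
        t = np.arange(0, 6, 0.01)
        assert len(build_pair_segments(c, t)) == 9

    def test_three_crossings_give_one_segment(self):
        t = np.arange(0, 2, 0.01)
        assert len(build_pair_segments(np.array([0.2, 0.7, 1.2]), t)) == 1

    def test_adjacent_segments_share_one_oscillation(self):
        c = np.arange(8) * 0.4
        t = np.arange(0, 4, 0.01)
        segs = build_pair_segments(c, t)
        for a, b in zip(segs, segs[1:]):
            assert a.osc_indices[1] == b.osc_indices[0]
            # segment k ends where oscillation k+1 ends, segment k+1
            # starts where oscillation k+1 starts
            assert a.t_end == c[a.osc_indices[1] + 1]
            assert b.t_start == c[b.osc_indices[0]]

    def test_too_few_crossings_rejected(self):
        with pytest.raises(OscillationError):
            build_pair_segments(np.array([0.1, 0.5]), np.arange(0, 1, 0.01))

    @settings(derandomize=True, max_examples=49)
    @given(st.integers(2, 50))
    def test_count_law_n_minus_one(self, n_osc):
        """n oscillations always yield exactly n − 1 pair segments."""
        t = np.arange(0, (n_osc + 2) * 0.5 + 0.3, 0.01)
        y = np.sin(2 * np.pi * t)  # crossings every 0.5 s
        c = zero_crossings(y, t)
        assert c.size >= n_osc + 1
        segs = build_pair_segments(c[:n_osc + 1], t)
        assert len(segs) == n_osc - 1


class TestSumOfSinesFit:
    def test_single_term_exact_recovery(self):
        t = np.arange(0, 4, 0.01)
        fit = fit_sum_of_sines(2.0 * np.sin(3.0 * t + 0.5), t, 1)
        assert abs(fit.a[0] - 2.0) < 2e-4
        assert abs(fit.b[0] - 3.0) < 3e-4
        assert abs(fit.c[0] - 0.5) < 1e-3
        assert fit.r_squared >= 0.9999

    def test_three_term_nested_on_single_sine(self):
        t = np.arange(0, 4, 0.01)
        fit = fit_sum_of_sines(2.0 * np.sin(3.0 * t + 0.5), t, 3)
        assert fit.r_squared >= 0.9999

    def test_three_term_exact_recovery(self):
        t = np.arange(0, 6, 0.01)
        y = (2.0 * np.sin(3.0 * t + 0.5) + 0.5 * np.sin(6.0 * t + 0.3)
             + 0.2 * np.sin(9.0 * t + 0.1))
        fit = fit_sum_of_sines(y, t, 3)
        assert fit.r_squared >= 0.9999
        np.testing.assert_allclose(fit.a, [2.0, 0.5, 0.2], rtol=1e-3)
        np.testing.assert_allclose(fit.b, [3.0, 6.0, 9.0], rtol=1e-3)

    def test_heavy_noise_degrades_r_squared(self):
        t = np.arange(0, 4, 0.01)
        y = np.sin(3.0 * t)
        rng = np.random.default_rng(12)
        noisy = y + rng.normal(0, np.std(y), y.size)  # SNR 0 dB
        r_clean = fit_sum_of_sines(y, t, 1).r_squared
        r_noisy = fit_sum_of_sines(noisy, t, 1).r_squared
        assert r_noisy < 0.9
        assert r_noisy < r_clean

    def test_nesting_never_violated_on_noisy_segments(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 1.5, 0.01)
        for _ in range(30):
            y = (rng.uniform(0.5, 3) * np.sin(rng.uniform(2, 8) * t
                                              + rng.uniform(-3, 3))
                 + rng.normal(0, 0.5, t.size))
            r1 = fit_sum_of_sines(y, t, 1).r_squared
            r3 = fit_sum_of_sines(y, t, 3).r_squared
            assert r3 >= r1 - 1e-9

    def test_segment_too_short_rejected(self):
        with pytest.raises(InputError):
            fit_sum_of_sines(np.ones(8), np.arange(8) / 100.0, 1)


class TestRotationAngle:
    def test_constant_rate_integral(self):
        t = np.arange(0, 1.01, 0.01)
        ang = rotation_angle(np.full(t.size, 100.0), t)
        assert abs(ang[-1] - 100.0) < 1e-9

    def test_full_cycle_nets_zero(self):
        t = np.arange(0, 1.0, 0.001)
        ang = rotation_angle(100 * np.sin(2 * np.pi * t), t)
        assert abs(ang[-1]) < 0.1
        assert ang.max() - ang.min() > 10

    def test_matches_oversampled_reference(self):
        t = np.arange(0, 2, 0.01)
        tf = np.arange(0, 2, 0.001)
        f = lambda x: 200 * np.sin(2 * np.pi * 1.3 * x) * np.exp(-0.2 * x)
        coarse = rotation_angle(f(t), t)
        fine = rotation_angle(f(tf), tf)
        ref = fine[::10][coarse.size - 1]
        assert abs(coarse[-1] - ref) <= abs(0.005 * (fine.max() - fine.min()))


def _oracle_features(y, t):
    """Straight-line re-implementation of the feature aggregation (naive
    loops, no shared aggregation code; only the nonlinear sine fit itself is
    reused, since an optimizer cannot be re-derived to 1e-9)."""
    # naive sign-change crossings with linear interpolation
    crossings = []
    for j in range(y.size - 1):
        if (y[j] >= 0) != (y[j + 1] >= 0):
            frac = -y[j] / (y[j + 1] - y[j])
            crossings.append(t[j] + frac * (t[j + 1] - t[j]))
    segs = []
    for k in range(len(crossings) - 2):
        lo = next(i for i in range(y.size) if t[i] >= crossings[k])
        hi = max(i for i in range(y.size) if t[i] <= crossings[k + 2]) + 1
        segs.append((lo, hi))
    max_rate, ptp, q75, r1, r3 = [], [], [], [], []
    for lo, hi in segs:
        yy, tt = y[lo:hi], t[lo:hi]
        ang = [0.0]
        for j in range(1, yy.size):
            ang.append(ang[-1] + 0.5 * (yy[j] + yy[j - 1]) * (tt[j] - tt[j - 1]))
        ang = np.array(ang)
        max_rate.append(max(abs(v) for v in yy))
        ptp.append(ang.max() - ang.min())
        q75.append(np.percentile(ang, 75))
        r1.append(fit_sum_of_sines(yy, tt, 1).r_squared)
        r3.append(fit_sum_of_sines(yy, tt, 3).r_squared)
    m = len(segs)
    k = m // 3
    return {
        "mean_angRate": float(np.mean(max_rate)),
        "median_rotAngle": float(np.median(ptp)),
        "upQuart_rotAngle": float(np.mean(q75)),
        "ratioQ13_angRate": float(np.mean(max_rate[:k]) / np.mean(max_rate[-k:])),
        "ratioQ13_rotAngle": float(np.mean(ptp[:k]) / np.mean(ptp[-k:])),
        "std_rsquare_1n": float(np.std(r1, ddof=1)),
        "mean_rsquare_3n": float(np.mean(r3)),
        "std_rsquare_3n": float(np.std(r3, ddof=1)),
    }


def _noisy_fixture():
    t = np.arange(0, 8, 0.01)
    rng = np.random.default_rng(21)
    y = 280 * np.sin(2 * np.pi * 1.4 * t) * (1 - 0.03 * t)
    return y + rng.normal(0, 2.8, y.size), t


class TestComputeFeatures:
    def test_forced_values_constant_sinusoid(self, sine_ps):
        y, t = sine_ps
        fv = compute_features(y, t)
        assert abs(fv.mean_angRate - 300.0) < 1.0
        assert abs(fv.ratioQ13_angRate - 1.0) < 0.01
        assert fv.std_rsquare_1n < 1e-4
        assert fv.mean_rsquare_3n > 0.9999

    def test_forced_ratio_two_for_halved_envelope(self):
        t = np.arange(0, 12, 0.01)
        env = np.where(t < 4.8, 300.0,
                       np.where(t > 7.2, 150.0,
                                300.0 - 62.5 * (t - 4.8)))
        y = env * np.sin(2 * np.pi * 1.25 * t)
        fv = compute_features(y, t)
        assert abs(fv.ratioQ13_angRate - 2.0) < 0.05

    def test_dual_implementation_oracle_agreement(self):
        y, t = _noisy_fixture()
        fv = compute_features(y, t).as_dict()
        ref = _oracle_features(y, t)
        for name in FEATURE_NAMES:
            assert abs(fv[name] - ref[name]) <= 1e-9 * max(1.0, abs(ref[name])), name

    def test_scale_equivariance(self):
        y, t = _noisy_fixture()
        base = compute_features(y, t).as_dict()
        scaled = compute_features(3.0 * y, t).as_dict()
        for name in ("mean_angRate", "median_rotAngle", "upQuart_rotAngle"):
            assert abs(scaled[name] - 3.0 * base[name]) < 1e-9 * abs(base[name]) * 3
        for name in ("ratioQ13_angRate", "ratioQ13_rotAngle"):
            assert abs(scaled[name] - base[name]) < 1e-9
        for name in ("std_rsquare_1n", "mean_rsquare_3n", "std_rsquare_3n"):
            assert abs(scaled[name] - base[name]) < 1e-6

    def test_too_few_segments_rejected(self):
        t = np.arange(0, 1.0, 0.01)
        with pytest.raises((FeatureError, OscillationError)):
            compute_features(300 * np.sin(2 * np.pi * t), t)

    def test_registered_extra_feature(self, sine_ps):
        y, t = sine_ps
        register_feature("n_segments", lambda stats: len(stats["max_rate"]))
        try:
            fv = compute_features(y, t)
            assert fv.extras["n_segments"] >= 4
        finally:
            from pronosup.features import _EXTRA_FEATURES
            _EXTRA_FEATURES.pop("n_segments", None)


def test_severity_monotonicity_over_corpus(severity_corpus):
    """Across the severity grid, the class mean of the speed feature falls
    and the class mean of the rhythm-variation feature rises — the signs of
    their clinical correlations."""
    df = severity_corpus["features"]
    sub = df.groupby("label").head(50)
    speed = [sub[sub.label == c]["mean_angRate"].mean() for c in range(5)]
    rhythm = [sub[sub.label == c]["std_rsquare_1n"].mean() for c in range(5)]
    assert all(a > b for a, b in zip(speed, speed[1:]))
    assert all(a < b for a, b in zip(rhythm, rhythm[1:]))
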
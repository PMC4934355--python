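"""Low-pass filtering, Madgwick fusion, Euler conversion, resampling."""

from dataclasses import replace
from math import pi, radians

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pronosup as p
from pronosup.errors import InputError, ParameterError
from pronosup.orientation import (FusionConfig, OrientationTrace,
                                  estimate_orientation, from_euler, lowpass,
                                  madgwick_step, orientation_from_accel_mag,
                                  quat_angle_deg, quat_conjugate, quat_multiply,
                                  quat_rotate, resample_spline, to_euler)
from pronosup.signal_io import ImuTrace, Placement
from pronosup.synth import MAG_REFERENCE_UT


def _static_trace(n=500, fs=100.0):
    t = np.arange(n) / fs
    return ImuTrace(t=t,
                    accel=np.tile([0.0, 0.0, 1.0], (n, 1)),
                    gyro=np.zeros((n, 3)),
                    mag=np.tile(MAG_REFERENCE_UT, (n, 1)),
                    placement=Placement.WRIST_RIGHT)


class TestLowpass:
    def test_constant_signal_unchanged(self):
        tr = _static_trace()
        out = lowpass(tr, FusionConfig())
        np.testing.assert_allclose(out.accel, tr.accel, atol=1e-9)

    def test_high_frequency_attenuated_40db(self):
        fs, n = 100.0, 2048
        t = np.arange(n) / fs
        sig = np.sin(2 * pi * 1.0 * t) + np.sin(2 * pi * 40.0 * t)
        tr = ImuTrace(t=t, accel=np.zeros((n, 3)),
                      gyro=np.column_stack([sig, np.zeros((n, 2))]),
                      mag=np.full((n, 3), 20.0),
                      placement=Placement.WRIST_RIGHT)
        out = lowpass(tr, FusionConfig(lowpass_cutoff=10.0))
        spec_in = np.abs(np.fft.rfft(sig))
        spec_out = np.abs(np.fft.rfft(out.gyro[:, 0]))
        k40 = int(round(40.0 * n / fs))
        atten_db = 20 * np.log10(spec_in[k40] / spec_out[k40])
        assert atten_db >= 40.0

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        n = 2000
        tr = _static_trace(n)
        noisy = ImuTrace(t=tr.t, accel=tr.accel,
                         gyro=rng.normal(0, 5, (n, 3)), mag=tr.mag,
                         placement=tr.placement)
        out = lowpass(noisy, FusionConfig())
        assert out.gyro[:, 0].var() < noisy.gyro[:, 0].var()

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            lowpass(_static_trace(), FusionConfig(lowpass_cutoff=60.0))


class TestMadgwickStep:
    def test_equilibrium_is_fixed_point(self):
        q = np.array([1.0, 0, 0, 0])
        for _ in range(100):
            q = madgwick_step(q, (0, 0, 0), (0, 0, 1.0),
                              tuple(MAG_REFERENCE_UT), 0.041, 0.01)
        assert quat_angle_deg(q, [1, 0, 0, 0]) < 1e-6

    def test_beta_zero_matches_closed_form_integration(self):
        """Pure gyro integration of 90°/s about z for 1 s at 1 kHz."""
        q = np.array([1.0, 0, 0, 0])
        for _ in range(1000):
            q = madgwick_step(q, (0, 0, pi / 2), (0, 0, 0), (0, 0, 0),
                              0.0, 0.001)
        q_closed = np.array([np.cos(pi / 4), 0, 0, np.sin(pi / 4)])
        assert quat_angle_deg(q, q_closed) < 0.1

    @pytest.mark.parametrize("err0_deg", [5.0, 10.0, 15.0])
    def test_static_convergence_small_errors(self, err0_deg):
        """β = 0.041 pulls a perturbed estimate below 1° within 5 s.

        The normalized-gradient correction limits the convergence rate to
        ≈ 2β rad/s, so 15° is about the largest error removable in 5 s.
        """
        axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        th = radians(err0_deg)
        q = np.array([np.cos(th / 2), *np.sin(th / 2) * axis])
        for _ in range(500):
            q = madgwick_step(q, (0, 0, 0), (0, 0, 1.0),
                              tuple(MAG_REFERENCE_UT), 0.041, 0.01)
        assert quat_angle_deg(q, [1, 0, 0, 0]) < 1.0

    def test_zero_accel_degrades_to_gyro_only(self):
        q0 = np.array([1.0, 0, 0, 0])
        q_a = madgwick_step(q0, (0.1, 0.2, 0.3), (0, 0, 0), (0, 0, 0),
                            0.041, 0.01)
        q_b = madgwick_step(q0, (0.1, 0.2, 0.3), (0, 0, 1), (20, 0, -44),
                            0.0, 0.01)
        np.testing.assert_allclose(q_a, q_b, atol=1e-12)

    def test_unit_norm_preserved(self):
        rng = np.random.default_rng(3)
        q = np.array([1.0, 0, 0, 0])
        for _ in range(200):
            q = madgwick_step(q, rng.normal(0, 2, 3), rng.normal(0, 1, 3),
                              rng.normal(0, 30, 3), 0.041, 0.01)
            assert abs(np.linalg.norm(q) - 1.0) < 1e-6


class TestEstimateOrientation:
    def test_static_trace_level(self):
        ot = estimate_orientation(_static_trace())
        eul = ot.euler_deg()
        assert np.max(np.abs(eul[:, :2])) < 1.0  # roll and pitch near 0

    def test_too_short_trace_rejected(self):
        tr = _static_trace(9)
        with pytest.raises(InputError):
            estimate_orientation(tr)

    def test_noiseless_synth_tracks_truth(self, rec_class0_noiseless):
        rec = rec_class0_noiseless
        ot = estimate_orientation(rec.recording.wrist_trace(), FusionConfig())
        errs = [quat_angle_deg(ot.q[i], rec.truth_quat.q[i])
                for i in range(100, len(ot))]  # 1 s warm-up
        assert np.mean(errs) < 2.0

    def test_noisy_synth_within_regression_threshold(self, rec_class0):
        """Frozen baseline: default sensor noise keeps the mean geodesic
        error (after 1 s warm-up) under 4°."""
        rec = rec_class0
        ot = estimate_orientation(rec.recording.wrist_trace(), FusionConfig())
        errs = [quat_angle_deg(ot.q[i], rec.truth_quat.q[i])
                for i in range(100, len(ot))]
        assert np.mean(errs) < 4.0

    def test_initialization_from_accel_mag(self):
        q_true = from_euler(30.0, 20.0, 50.0)
        a = quat_rotate(quat_conjugate(q_true), [0, 0, 1.0])
        m = quat_rotate(quat_conjugate(q_true), MAG_REFERENCE_UT)
        q0 = orientation_from_accel_mag(a, m)
        assert quat_angle_deg(q0, q_true) < 1e-4


class TestEuler:
    def test_identity(self):
        (r, pit, y), gimbal = to_euler([1.0, 0, 0, 0])
        assert (r, pit, y) == (0.0, 0.0, 0.0)
        assert not gimbal

    def test_pure_pitch_45(self):
        (_, pit, _), _ = to_euler(from_euler(0.0, 45.0, 0.0))
        assert abs(pit - 45.0) < 1e-6

    def test_gimbal_flagged(self):
        _, gimbal = to_euler(from_euler(0.0, 89.95, 0.0))
        assert gimbal

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-179, 179), st.floats(-85, 85), st.floats(-179, 179))
    def test_roundtrip(self, roll, pitch, yaw):
        (r, pit, y), _ = to_euler(from_euler(roll, pitch, yaw))
        # compare as rotations, not raw angles (angle aliasing)
        assert quat_angle_deg(from_euler(r, pit, y),
                              from_euler(roll, pitch, yaw)) < 1e-4


def _slerp(qa, qb, frac):
    d = float(np.dot(qa, qb))
    if d < 0:
        qb, d = -qb, -d
    d = min(d, 1.0)
    th = np.arccos(d)
    if th < 1e-9:
        return qa
    return (np.sin((1 - frac) * th) * qa + np.sin(frac * th) * qb) / np.sin(th)


class TestResample:
    def test_frame_count_100_to_60_hz(self):
        t = np.arange(1000) / 100.0
        ot = OrientationTrace(t=t, q=np.tile([1.0, 0, 0, 0], (1000, 1)))
        assert len(resample_spline(ot, 60.0)) == 600

    def test_constant_quaternion_preserved(self):
        t = np.arange(100) / 100.0
        q = from_euler(10, 20, 30)
        ot = OrientationTrace(t=t, q=np.tile(q, (100, 1)))
        out = resample_spline(ot, 60.0)
        for qi in out.q:
            assert quat_angle_deg(qi, q) < 1e-9

    def test_slow_rotation_matches_slerp(self):
        t = np.arange(200) / 100.0
        q = np.array([from_euler(30.0 * np.sin(0.5 * ti), 0, 0) for ti in t])
        ot = OrientationTrace(t=t, q=q)
        out = resample_spline(ot, 60.0)
        for ti, qi in zip(out.t, out.q):
            i = np.searchsorted(t, ti) - 1
            i = max(0, min(i, len(t) - 2))
            frac = (ti - t[i]) / (t[i + 1] - t[i])
            ref = _slerp(q[i], q[i + 1], frac)
            assert quat_angle_deg(qi, ref) < 0.5

    def test_too_few_samples_rejected(self):
        ot = OrientationTrace(t=np.arange(3) / 100.0,
                              q=np.tile([1.0, 0, 0, 0], (3, 1)))
        with pytest.raises(InputError):
            resample_spline(ot, 60.0)

    def test_unit_norm_output(self, rec_class0):
        ot = estimate_orientation(rec_class0.recording.wrist_trace())
        out = resample_spline(ot, 60.0)
        np.testing.assert_allclose(np.linalg.norm(out.q, axis=1), 1.0,
                                   atol=1e-9)
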
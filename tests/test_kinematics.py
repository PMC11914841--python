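"""Kinematic engine tests: filter response, speed, path error, SAT, SPARC.

SPARC values are checked against an independent brute-force oracle that
computes the spectrum by direct DFT summation and the arc length by
explicit quadrature over the spectral curve.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vrmotorlab.errors import IntegrityError, ParameterError
from vrmotorlab.io_session import Trajectory
from vrmotorlab.kinematics import (
    CircleShape,
    LineShape,
    SpeedSeries,
    analyze_task,
    butterworth_gain,
    compute_sat,
    lowpass_filter,
    path_error,
    sparc,
    speed_profile,
    speed_spectrum,
)
from vrmotorlab.synthetic import TrajectoryGenSpec, generate_trajectory, min_jerk_speed


def _traj_from_x(x, rate=60.0):
    t = np.arange(len(x)) / rate
    xyz = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    return Trajectory(t=t, xyz=xyz, nominal_rate=rate)


def _sine_amplitude(x, f_hz, rate=60.0):
    """LS amplitude of a sinusoid at f_hz, interior samples only."""
    n = len(x)
    sl = slice(n // 4, 3 * n // 4)
    t = np.arange(n)[sl] / rate
    c = np.cos(2 * np.pi * f_hz * t)
    s = np.sin(2 * np.pi * f_hz * t)
    xs = x[sl]
    return 2.0 * abs(np.mean(xs * s) + 1j * np.mean(xs * c))


# --- oracle: brute-force DFT + arc-length quadrature -----------------------

def dft_magnitude_oracle(v, nfft):
    """O(n^2) direct DFT magnitude on the rfft frequency grid."""
    v = np.asarray(v, float)
    k = np.arange(nfft // 2 + 1)
    n = np.arange(len(v))
    basis = np.exp(-2j * np.pi * np.outer(k, n) / nfft)
    return np.abs(basis @ v)


def sparc_oracle(t, v, amp_threshold=0.05, max_cutoff_hz=20.0, pad_factor=4):
    """Independent SPARC: direct DFT, explicit threshold scan and quadrature."""
    dt = float(np.median(np.diff(t)))
    nfft = pad_factor * (1 << int(len(v) - 1).bit_length())
    mag = dft_magnitude_oracle(v, nfft)
    mag = mag / mag[0]
    freqs = np.arange(len(mag)) / (nfft * dt)
    keep = [i for i in range(len(freqs)) if freqs[i] <= max_cutoff_hz]
    f, m = freqs[keep], mag[keep]
    last = 0
    for i in range(len(m)):
        if m[i] >= amp_threshold:
            last = i
    stop = max(last + 1, 2)
    f, m = f[:stop], m[:stop]
    span = f[-1] - f[0]
    total = 0.0
    for i in range(1, len(f)):
        total += math.hypot((f[i] - f[i - 1]) / span, m[i] - m[i - 1])
    return -total


# --- filtering -------------------------------------------------------------

class TestLowpassFilter:
    def test_constant_position_is_preserved(self):
        x = np.full(200, 0.42)
        out = lowpass_filter(_traj_from_x(x))
        np.testing.assert_allclose(out.xyz[:, 0], 0.42, atol=1e-9)

    @pytest.mark.parametrize("f_hz", [1.0, 2.0, 5.0])
    def test_passband_sinusoid_matches_squared_analytic_response(self, f_hz):
        # zero-phase filtering applies the Butterworth magnitude twice
        x = np.sin(2 * np.pi * f_hz * np.arange(1200) / 60.0)
        out = lowpass_filter(_traj_from_x(x), cutoff_hz=10.0, order=4)
        ratio = _sine_amplitude(out.xyz[:, 0], f_hz) / _sine_amplitude(x, f_hz)
        expected = butterworth_gain(f_hz, 10.0, 4, passes=2)
        assert ratio == pytest.approx(expected, rel=0.01)

    def test_stopband_25hz_attenuated_below_analytic_bound(self):
        x = np.sin(2 * np.pi * 25.0 * np.arange(1200) / 60.0)
        out = lowpass_filter(_traj_from_x(x), cutoff_hz=10.0, order=4)
        bound = butterworth_gain(25.0, 10.0, 4, passes=2)
        assert _sine_amplitude(out.xyz[:, 0], 25.0) <= bound + 1e-6

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            lowpass_filter(_traj_from_x(np.zeros(100) + 0.1), cutoff_hz=30.0)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ParameterError, match="warm-up"):
            lowpass_filter(_traj_from_x(np.zeros(10) + 0.1))

    def test_passband_limited_signal_nearly_unchanged(self):
        # filter is ~idempotent on a signal already below the cutoff
        rng = np.random.default_rng(0)
        t = np.arange(600) / 60.0
        x = sum(rng.normal() * np.sin(2 * np.pi * f * t) for f in (0.5, 1.5, 3.0))
        once = lowpass_filter(_traj_from_x(x)).xyz[:, 0]
        twice = lowpass_filter(_traj_from_x(once)).xyz[:, 0]
        rms = np.sqrt(np.mean((twice - once) ** 2)) / np.sqrt(np.mean(once**2))
        assert rms < 0.01


class TestSpeedProfile:
    def test_uniform_motion_recovers_constant_speed(self):
        x = 0.3 * np.arange(300) / 60.0
        v = speed_profile(_traj_from_x(x)).v
        np.testing.assert_allclose(v[1:-1], 0.3, atol=1e-9)

    def test_stationary_trajectory_has_zero_speed(self):
        v = speed_profile(_traj_from_x(np.full(100, 0.2))).v
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_minimum_jerk_peak_speed_closed_form(self, line_shape):
        # peak speed of a point-to-point minimum-jerk move is 1.875 D / T
        traj = generate_trajectory(
            TrajectoryGenSpec(shape=line_shape, duration_s=2.0)
        )
        v = speed_profile(traj).v
        assert v.max() == pytest.approx(1.875 * 0.3 / 2.0, rel=0.01)

    def test_gap_beyond_tolerance_requires_resampling(self):
        t = np.arange(100) / 60.0
        t[50:] += 0.1  # a dropped chunk
        xyz = np.column_stack([t, t * 0, t * 0])
        traj = Trajectory(t=t, xyz=xyz)
        with pytest.raises(IntegrityError):
            speed_profile(traj)
        out = speed_profile(traj, resample=True)
        assert np.all(np.isfinite(out.v))


class TestPathError:
    def test_samples_on_ideal_line_give_zero(self, line_shape):
        s = np.linspace(0, 1, 100)
        xyz = np.outer(s, np.array([0.3, 0, 0]))
        traj = Trajectory(t=np.arange(100) / 60.0, xyz=xyz)
        assert path_error(traj, line_shape) == pytest.approx(0.0, abs=1e-7)

    def test_parallel_offset_line_reports_the_offset(self, line_shape):
        s = np.linspace(0, 1, 100)
        xyz = np.outer(s, np.array([0.3, 0, 0])) + np.array([0, 0.01, 0])
        traj = Trajectory(t=np.arange(100) / 60.0, xyz=xyz)
        assert path_error(traj, line_shape) == pytest.approx(1.0, rel=1e-6)

    def test_inflated_circle_reports_radial_offset(self, circle_shape):
        theta = np.linspace(0, 2 * np.pi, 200)
        r = circle_shape.r + 0.005
        xyz = np.column_stack([r * np.cos(theta), r * np.sin(theta), 0 * theta])
        traj = Trajectory(t=np.arange(200) / 60.0, xyz=xyz, task="circle")
        assert path_error(traj, circle_shape) == pytest.approx(0.5, rel=1e-6)

    def test_task_shape_mismatch_rejected(self, circle_shape, clean_line_trajectory):
        with pytest.raises(ParameterError, match="match"):
            path_error(clean_line_trajectory, circle_shape)

    def test_path_length_ratio_alternative(self, line_shape, clean_line_trajectory):
        # a clean trace travels the ideal length: zero excess path
        assert path_error(
            clean_line_trajectory, line_shape, method="path_length_ratio"
        ) == pytest.approx(0.0, abs=0.5)
        wiggly = generate_trajectory(
            TrajectoryGenSpec(shape=line_shape, duration_s=2.0, deviation_amp_cm=3.0)
        )
        assert path_error(wiggly, line_shape, method="path_length_ratio") > 5.0
        with pytest.raises(ParameterError, match="method"):
            path_error(clean_line_trajectory, line_shape, method="nope")


class TestSAT:
    def test_direct_ratio_of_speed_and_error(self, line_shape):
        # constant 0.3 m/s along the line, offset 10 cm -> SAT = 30/10
        s = np.linspace(0, 1, 121)
        xyz = np.outer(s, np.array([0.3, 0, 0])) + np.array([0, 0.1, 0])
        traj = Trajectory(t=np.arange(121) / 60.0, xyz=xyz)
        assert compute_sat(traj, line_shape) == pytest.approx(
            (0.3 / 2.0 * 100) / 10.0, rel=1e-6
        )

    def test_error_floor_guards_perfect_traces(self, line_shape):
        s = np.linspace(0, 1, 121)
        xyz = np.outer(s, np.array([0.3, 0, 0]))
        traj = Trajectory(t=np.arange(121) / 60.0, xyz=xyz)
        assert compute_sat(traj, line_shape, error_floor_cm=0.1) == pytest.approx(
            (0.3 / 2.0 * 100) / 0.1, rel=1e-6
        )

    def test_time_compression_doubles_sat(self, line_shape, clean_line_trajectory):
        traj = clean_line_trajectory
        fast = Trajectory(
            t=traj.t[::2] / 2.0,
            xyz=traj.xyz[::2],
            nominal_rate=traj.nominal_rate,
            task=traj.task,
        )
        slow_sat = compute_sat(traj, line_shape)
        fast_sat = compute_sat(fast, line_shape)
        assert fast_sat == pytest.approx(2.0 * slow_sat, rel=0.01)


class TestSpeedSpectrum:
    def test_constant_speed_concentrates_at_dc(self):
        t = np.arange(64) / 60.0
        spec = speed_spectrum(SpeedSeries(t=t, v=np.full(64, 0.3)))
        assert spec.vhat[0] == pytest.approx(1.0)
        # windowed-constant spectrum is a sinc: beyond ten pre-padding bin
        # widths its envelope has decayed below 1/(10*pi)
        far = spec.omega > 10 * (60.0 / 64)
        assert np.all(spec.vhat[far] < 0.05)
        # and the bulk of the curve is gone right after the mainlobe
        assert np.all(spec.vhat[spec.omega > 60.0 / 64] < 0.25)

    def test_two_burst_profile_matches_direct_dft_oracle(self):
        t = np.arange(120) / 60.0
        v = np.exp(-0.5 * ((t - 0.5) / 0.1) ** 2) + 0.7 * np.exp(
            -0.5 * ((t - 1.4) / 0.15) ** 2
        )
        spec = speed_spectrum(SpeedSeries(t=t, v=v), pad_factor=4)
        nfft = 4 * 128
        oracle = dft_magnitude_oracle(v, nfft)
        oracle = oracle / oracle[0]
        np.testing.assert_allclose(spec.vhat, oracle, atol=1e-9)

    def test_amplitude_scaling_leaves_spectrum_unchanged(self):
        t = np.arange(64) / 60.0
        v = min_jerk_speed(t / t[-1])
        a = speed_spectrum(SpeedSeries(t=t, v=v)).vhat
        b = speed_spectrum(SpeedSeries(t=t, v=3.7 * v)).vhat
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_all_zero_speed_rejected(self):
        t = np.arange(64) / 60.0
        with pytest.raises(ParameterError):
            speed_spectrum(SpeedSeries(t=t, v=np.zeros(64)))


class TestSparc:
    def test_matches_arc_length_quadrature_oracle(self):
        t = np.arange(120) / 60.0
        v = min_jerk_speed(t / t[-1])
        assert sparc(SpeedSeries(t=t, v=v)) == pytest.approx(
            sparc_oracle(t, v), abs=1e-6
        )

    def test_two_submovements_less_smooth_than_one(self, line_shape):
        single = generate_trajectory(
            TrajectoryGenSpec(shape=line_shape, duration_s=2.0, n_submovements=1)
        )
        double = generate_trajectory(
            TrajectoryGenSpec(shape=line_shape, duration_s=2.0, n_submovements=2)
        )
        s1 = sparc(speed_profile(single))
        s2 = sparc(speed_profile(double))
        assert s2 < s1 <= 0.0

    @given(scale=st.floats(min_value=0.05, max_value=50.0))
    def test_amplitude_scaling_invariance(self, scale):
        t = np.arange(90) / 60.0
        v = min_jerk_speed(t / t[-1]) + 0.01
        assert sparc(SpeedSeries(t=t, v=scale * v)) == pytest.approx(
            sparc(SpeedSeries(t=t, v=v)), abs=1e-12
        )

    def test_time_shift_invariance(self):
        t = np.arange(150) / 60.0
        v = np.zeros(150)
        v[10:70] = min_jerk_speed(np.linspace(0, 1, 60))
        w = np.zeros(150)
        w[60:120] = min_jerk_speed(np.linspace(0, 1, 60))
        assert sparc(SpeedSeries(t=t, v=v)) == pytest.approx(
            sparc(SpeedSeries(t=t, v=w)), abs=1e-9
        )


class TestAnalyzeTask:
    def test_noiseless_minimum_jerk_line(self, line_shape, clean_line_trajectory):
        res = analyze_task(clean_line_trajectory, line_shape)
        assert res.error_cm < 0.05
        # error at the floor: SAT = mean speed / 0.1 cm
        assert res.sat == pytest.approx(res.mean_speed * 100 / 0.1, rel=1e-6)
        series = speed_profile(lowpass_filter(clean_line_trajectory))
        assert res.sparc == pytest.approx(sparc(series), abs=1e-12)

    def test_submovements_reduce_both_smoothness_and_sat(self, line_shape):
        clean = analyze_task(
            generate_trajectory(TrajectoryGenSpec(shape=line_shape, duration_s=2.0)),
            line_shape,
        )
        frag = analyze_task(
            generate_trajectory(
                TrajectoryGenSpec(
                    shape=line_shape,
                    duration_s=2.0,
                    n_submovements=4,
                    deviation_amp_cm=1.0,
                )
            ),
            line_shape,
        )
        assert frag.sparc < clean.sparc
        assert frag.sat < clean.sat

    def test_stage_errors_carry_stage_name(self, line_shape):
        tiny = Trajectory(t=np.arange(10) / 60.0, xyz=np.zeros((10, 3)) + 0.1)
        with pytest.raises(ParameterError, match="lowpass_filter"):
            analyze_task(tiny, line_shape)
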
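"""Despiking, gap filling, filtering, resampling, and pass segmentation."""

import numpy as np
import pytest

from gaitkit import (
    GaitSpec,
    NoiseSpec,
    PreprocessConfig,
    despike_and_fill,
    downsample,
    lowpass_zero_lag,
    segment_passes,
    simulate_gait,
    trim_sync,
)
from tests.conftest import make_traj


def _traj_1d(x, frame_rate=30.0, name="left_ankle"):
    pos = np.column_stack([x, np.zeros_like(x)])
    return make_traj({name: pos}, frame_rate=frame_rate)


class TestDespikeAndFill:
    def test_quadratic_below_threshold_unchanged(self):
        k = np.arange(40, dtype=float)
        traj = _traj_1d(k**2)
        cfg = PreprocessConfig(accel_threshold=10.0)  # second difference = 2
        out = despike_and_fill(traj, cfg)
        np.testing.assert_allclose(
            out.positions["left_ankle"], traj.positions["left_ankle"]
        )

    def test_spike_on_line_refilled(self):
        x = np.arange(50, dtype=float)
        x[20] += 50.0
        out = despike_and_fill(_traj_1d(x), PreprocessConfig(accel_threshold=10.0))
        np.testing.assert_allclose(
            out.positions["left_ankle"][:, 0], np.arange(50, dtype=float), atol=1e-6
        )

    def test_cubic_gap_refilled_exactly(self):
        # a cubic spline interpolant reproduces cubic polynomials exactly
        k = np.arange(60, dtype=float)
        poly = 0.001 * k**3 - 0.2 * k**2 + 3.0 * k + 7.0
        traj = _traj_1d(poly)
        traj.set_gap("left_ankle", np.array([25, 26, 27]))
        out = despike_and_fill(traj, PreprocessConfig(accel_threshold=1e9))
        np.testing.assert_allclose(
            out.positions["left_ankle"][:, 0], poly, atol=1e-9
        )

    def test_long_gap_left_unfilled(self):
        x = np.sin(np.arange(100) / 5.0)
        traj = _traj_1d(x)
        traj.set_gap("left_ankle", np.arange(40, 60))
        out = despike_and_fill(
            traj, PreprocessConfig(accel_threshold=1e9, max_gap_frames=10)
        )
        assert not out.valid_mask("left_ankle")[40:60].any()

    def test_endpoint_gaps_never_extrapolated(self):
        x = np.arange(30, dtype=float)
        traj = _traj_1d(x)
        traj.set_gap("left_ankle", np.array([0, 1, 29]))
        out = despike_and_fill(traj, PreprocessConfig(accel_threshold=1e9))
        assert not out.valid_mask("left_ankle")[[0, 1, 29]].any()

    def test_too_few_samples_passes_through_with_warning(self):
        traj = _traj_1d(np.array([1.0, 2.0, 3.0]))
        out = despike_and_fill(traj, PreprocessConfig(accel_threshold=10.0))
        assert out.meta["preprocess_warnings"]
        np.testing.assert_allclose(
            out.positions["left_ankle"], traj.positions["left_ankle"]
        )

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(5)
        x = 50 * np.sin(np.arange(200) * 0.2) + rng.normal(0, 0.5, 200)
        x[[30, 90, 150]] += np.array([60, -80, 45])
        once = despike_and_fill(_traj_1d(x))
        twice = despike_and_fill(once)
        np.testing.assert_allclose(
            once.positions["left_ankle"], twice.positions["left_ankle"],
            atol=1e-9, equal_nan=True,
        )


class TestLowpassZeroLag:
    def test_constant_invariant(self):
        out = lowpass_zero_lag(_traj_1d(np.full(100, 7.5)))
        np.testing.assert_allclose(out.positions["left_ankle"][:, 0], 7.5)

    def test_passband_amplitude_preserved(self):
        # analytic two-pass Butterworth gain at 1 Hz, 5 Hz cutoff, order 4:
        # 1 / (1 + (1/5)^8) — indistinguishable from unity
        t = np.arange(600) / 30.0
        x = 10 * np.sin(2 * np.pi * 1.0 * t)
        out = lowpass_zero_lag(_traj_1d(x))
        y = out.positions["left_ankle"][100:-100, 0]
        ratio = y.std() / x[100:-100].std()
        assert abs(ratio - 1.0) < 0.01

    def test_stopband_attenuation_matches_analytic_response(self):
        # analytic two-pass gain |H(f)|² = 1/(1 + (f/fc)^(2·order)); sampled
        # fast enough (240 Hz) that discretisation warping is negligible
        t = np.arange(4800) / 240.0
        x = np.sin(2 * np.pi * 10.0 * t)
        out = lowpass_zero_lag(_traj_1d(x, frame_rate=240.0))
        y = out.positions["left_ankle"][800:-800, 0]
        expected = 1.0 / (1.0 + (10.0 / 5.0) ** 8)
        ratio = y.std() / x[800:-800].std()
        assert expected * 0.8 < ratio < expected * 1.2

    def test_stopband_attenuation_at_video_rate_at_least_analytic(self):
        # at 30 fps the discrete filter attenuates 10 Hz *more* than the
        # analog magnitude response (frequency warping toward Nyquist)
        t = np.arange(1200) / 30.0
        x = np.sin(2 * np.pi * 10.0 * t)
        out = lowpass_zero_lag(_traj_1d(x))
        y = out.positions["left_ankle"][200:-200, 0]
        analytic = 1.0 / (1.0 + (10.0 / 5.0) ** 8)
        assert y.std() / x[200:-200].std() < analytic

    def test_zero_phase_no_lag(self):
        t = np.arange(600) / 30.0
        x = np.sin(2 * np.pi * 2.0 * t) + 0.5 * np.sin(2 * np.pi * 3.7 * t)
        y = lowpass_zero_lag(_traj_1d(x)).positions["left_ankle"][:, 0]
        lags = np.arange(-10, 11)
        xc = [np.dot(x[50:-50], np.roll(y, k)[50:-50]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_commutes_with_constant_offset(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 300).cumsum()
        base = lowpass_zero_lag(_traj_1d(x)).positions["left_ankle"][:, 0]
        shifted = lowpass_zero_lag(_traj_1d(x + 123.0)).positions["left_ankle"][:, 0]
        np.testing.assert_allclose(shifted, base + 123.0, atol=1e-8)

    def test_remaining_gap_is_an_error(self):
        traj = _traj_1d(np.arange(100, dtype=float))
        traj.set_gap("left_ankle", np.array([50]))
        with pytest.raises(ValueError, match="gap"):
            lowpass_zero_lag(traj)


class TestDownsample:
    def test_240_to_30_decimation(self):
        x = np.arange(240, dtype=float)
        traj = _traj_1d(x, frame_rate=240.0)
        out = downsample(traj, 30.0)
        assert out.frame_rate == 30.0
        assert out.n_frames == 30
        np.testing.assert_allclose(
            out.positions["left_ankle"][:, 0], np.arange(0, 240, 8)
        )

    def test_identity_when_rates_match(self):
        traj = _traj_1d(np.arange(240, dtype=float), frame_rate=240.0)
        assert downsample(traj, 240.0).equals(traj)

    def test_non_divisible_linear_resampling_of_line(self):
        t = np.arange(100) / 100.0
        traj = _traj_1d(3.0 * t + 1.0, frame_rate=100.0)
        out = downsample(traj, 30.0)
        expected = 3.0 * out.times() + 1.0
        np.testing.assert_allclose(out.positions["left_ankle"][:, 0], expected, atol=1e-9)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample(_traj_1d(np.arange(10.0)), 60.0)

    def test_commutes_with_trim_on_aligned_windows(self):
        x = np.sin(np.arange(480) * 0.05)
        traj = _traj_1d(x, frame_rate=240.0)
        a = downsample(trim_sync(traj, 0.5, 1.5), 30.0)
        b = trim_sync(downsample(traj, 30.0), 0.5, 1.5)
        np.testing.assert_allclose(
            a.positions["left_ankle"], b.positions["left_ankle"], atol=1e-12
        )


class TestTrimSync:
    def test_full_window_identity(self):
        traj = _traj_1d(np.arange(90, dtype=float))
        assert trim_sync(traj, 0.0, traj.duration_s).equals(traj)

    def test_three_seconds_at_30fps(self):
        traj = _traj_1d(np.arange(300, dtype=float))
        out = trim_sync(traj, 2.0, 5.0)
        assert out.n_frames == 90
        assert out.frames[0] == 0

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            trim_sync(_traj_1d(np.arange(300.0)), 5.0, 2.0)


class TestSegmentPasses:
    @staticmethod
    def _walking_traj(x_hip):
        n = x_hip.size
        pos = {
            "left_hip": np.column_stack([x_hip, np.full(n, 100.0)]),
            "right_hip": np.column_stack([x_hip, np.full(n, 100.0)]),
        }
        return make_traj(pos, condition="overground_forward")

    def test_monotone_walk_single_pass(self):
        passes = self._walking_traj(np.arange(150, dtype=float))
        result = segment_passes(passes)
        assert len(result) == 1
        assert result[0][1] == "rightward"

    def test_out_and_back_two_passes(self):
        up = np.arange(100, dtype=float)
        x = np.concatenate([up, up[::-1]])
        result = segment_passes(self._walking_traj(x))
        assert [d for _, d in result] == ["rightward", "leftward"]

    def test_two_round_trips_four_passes(self):
        spec = GaitSpec(walk_mode="overground", n_round_trips=2)
        traj, truth = simulate_gait(spec, NoiseSpec.noiseless(), view="lateral", seed=4)
        result = segment_passes(traj)
        assert len(result) == len(truth.pass_bounds) == 4
        assert [d for _, d in result] == [d for _, _, d in truth.pass_bounds]
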
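"""Joint-angle geometry, range of motion, and angle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitkit import (
    GaitSpec,
    NoiseSpec,
    angle_agreement,
    joint_angle_series,
    normalize_cycles,
    range_of_motion,
    simulate_gait,
    three_point_angle,
)
from gaitkit.gait_events import GaitEvents
from gaitkit.kinematics import JointAngleSeries
from gaitkit.pipeline import preprocess_trajectory
from gaitkit.preprocess import PreprocessConfig
from tests.conftest import make_traj


def _acos_oracle(a, b, c):
    """Independent dot-product/acos formulation of the interior angle."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


class TestThreePointAngle:
    def test_collinear_is_180(self):
        assert three_point_angle([0, 0], [1, 0], [2, 0]) == pytest.approx(180.0)

    def test_right_angle(self):
        assert three_point_angle([0, 1], [0, 0], [1, 0]) == pytest.approx(90.0)

    def test_matches_trig_oracle_on_random_triplets(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a, b, c = rng.normal(0, 10, (3, 2))
            if min(np.linalg.norm(a - b), np.linalg.norm(c - b)) < 1e-6:
                continue
            assert three_point_angle(a, b, c) == pytest.approx(
                _acos_oracle(a, b, c), abs=1e-9
            )

    def test_coincident_points_undefined(self):
        assert np.isnan(three_point_angle([1, 1], [1, 1], [2, 2]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        pts=st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
            min_size=3, max_size=3,
        ),
        theta=st.floats(0, 2 * np.pi),
        scale=st.floats(0.01, 100.0),
        tx=st.floats(-1e3, 1e3),
        ty=st.floats(-1e3, 1e3),
    )
    def test_similarity_invariance_and_swap(self, pts, theta, scale, tx, ty):
        a, b, c = (np.array(p) for p in pts)
        if min(np.linalg.norm(a - b), np.linalg.norm(c - b)) < 1e-3:
            return
        base = three_point_angle(a, b, c)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        t = np.array([tx, ty])
        a2, b2, c2 = (scale * rot @ p + t for p in (a, b, c))
        assert three_point_angle(a2, b2, c2) == pytest.approx(base, abs=1e-6)
        assert three_point_angle(c, b, a) == pytest.approx(base, abs=1e-9)


class TestJointAngleSeries:
    def test_straight_standing_leg_reads_zero_knee(self):
        n = 5
        pos = {
            "left_hip": np.tile([100.0, 100.0], (n, 1)),
            "right_hip": np.tile([100.0, 100.0], (n, 1)),
            "left_knee": np.tile([100.0, 150.0], (n, 1)),
            "left_ankle": np.tile([100.0, 200.0], (n, 1)),
        }
        series = joint_angle_series(make_traj(pos), "knee", "left", direction=1.0)
        np.testing.assert_allclose(series.angles_deg, 0.0, atol=1e-9)

    def test_missing_landmark_named(self):
        pos = {"left_hip": np.zeros((5, 2)), "right_hip": np.zeros((5, 2))}
        with pytest.raises(ValueError, match="left_knee"):
            joint_angle_series(make_traj(pos), "knee", "left")

    def test_noiseless_lateral_recovery(self, clean_lateral):
        traj, truth = clean_lateral
        for joint in ("hip", "knee", "ankle"):
            series = joint_angle_series(traj, joint, "left")
            gt = truth.angles_deg[(joint, "left")]
            mae = np.nanmean(np.abs(series.angles_deg - gt))
            assert mae < 0.5, joint

    def test_frontal_view_degrades_sagittal_angles(self, clean_lateral, clean_frontal):
        lat_traj, truth = clean_lateral
        fro_traj, _ = clean_frontal
        gt = truth.angles_deg[("knee", "left")]
        lat = joint_angle_series(lat_traj, "knee", "left").angles_deg
        fro = joint_angle_series(fro_traj, "knee", "left").angles_deg
        n = min(gt.size, fro.size)
        lat_mae = np.nanmean(np.abs(lat[:n] - gt[:n]))
        fro_mae = np.nanmean(np.abs(fro[:n] - gt[:n]))
        assert lat_mae < fro_mae

    def test_angle_error_monotone_in_noise(self):
        spec = GaitSpec(bout_duration_s=10.0)
        maes = []
        for sigma in (0.0, 1.0, 2.0, 4.0):
            noise = NoiseSpec(
                jitter_sd_px=sigma, spike_rate=0.0, visibility_profile={},
                visibility_ar_sd=0.0,
            )
            traj, truth = simulate_gait(spec, noise, "lateral", seed=9)
            traj = preprocess_trajectory(traj, PreprocessConfig())
            series = joint_angle_series(traj, "knee", "left")
            gt = truth.angles_deg[("knee", "left")]
            maes.append(np.nanmean(np.abs(series.angles_deg - gt)))
        assert all(b >= a - 0.05 for a, b in zip(maes, maes[1:]))
        assert maes[-1] > maes[0]


class TestRangeOfMotion:
    @staticmethod
    def _events(n=5, stride=1.0):
        return GaitEvents("left", np.arange(n + 1) * stride, [])

    def test_constant_series_zero_rom(self):
        series = JointAngleSeries("knee", "left", np.full(150, 12.0), 30.0)
        rom = range_of_motion(series, self._events())
        assert rom.mean_deg == pytest.approx(0.0)

    def test_sinusoid_rom_twice_amplitude(self):
        t = np.arange(150) / 30.0
        series = JointAngleSeries("knee", "left", 20 * np.sin(2 * np.pi * t), 30.0)
        rom = range_of_motion(series, self._events())
        assert rom.mean_deg == pytest.approx(40.0, abs=0.5)

    def test_simulator_knee_rom_matches_truth(self, clean_lateral):
        traj, truth = clean_lateral
        series = joint_angle_series(traj, "knee", "left")
        rom = range_of_motion(series, truth.events_left)
        gt = truth.angles_deg[("knee", "left")]
        gt_rom = np.nanmax(gt) - np.nanmin(gt)
        assert rom.mean_deg == pytest.approx(gt_rom, abs=1.0)

    def test_no_complete_cycle_rejected(self):
        series = JointAngleSeries("knee", "left", np.zeros(30), 30.0)
        with pytest.raises(ValueError):
            range_of_motion(series, GaitEvents("left", [0.1], []))


class TestAngleAgreement:
    def test_identical_series(self):
        a = np.sin(np.arange(100) * 0.1)
        mae, r = angle_agreement(a, a.copy())
        assert mae == pytest.approx(0.0)
        assert r == pytest.approx(1.0)

    def test_constant_offset(self):
        a = 10 * np.sin(np.arange(100) * 0.1)
        mae, r = angle_agreement(a, a + 3.0)
        assert mae == pytest.approx(3.0)
        assert r == pytest.approx(1.0)

    def test_anticorrelation(self):
        a = np.sin(np.arange(100) * 0.1)
        _, r = angle_agreement(a, -a)
        assert r == pytest.approx(-1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            angle_agreement(np.zeros(10), np.zeros(11))


def test_normalize_cycles_shape(clean_lateral):
    traj, truth = clean_lateral
    series = joint_angle_series(traj, "knee", "left")
    traces = normalize_cycles(series, truth.events_left, n_points=101)
    assert traces.shape[1] == 101
    assert traces.shape[0] >= truth.events_left.n_strides - 2
    # every cycle spans roughly the same knee range
    assert np.ptp(traces.max(axis=1) - traces.min(axis=1)) < 5.0
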
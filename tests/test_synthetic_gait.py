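"""Simulator ground-truth consistency, determinism, and noise models."""

import numpy as np
import pytest

from gaitkit import (
    GaitSpec,
    NoiseSpec,
    pair_bilateral,
    simulate_cohort,
    simulate_gait,
    temporal_params,
)
from gaitkit.pipeline import RunConfig, analyze_trajectory
from gaitkit.synthetic_gait import VISIBILITY_PROFILES, max_step_length


class TestGroundTruth:
    def test_heel_strikes_exactly_periodic(self):
        spec = GaitSpec(stride_time=1.0, bout_duration_s=11.0)
        _, truth = simulate_gait(spec, NoiseSpec.noiseless(), "lateral", seed=0)
        hs = truth.events_left.heel_strikes
        assert hs.size >= 10
        np.testing.assert_allclose(np.diff(hs), 1.0, atol=1e-9)

    def test_truth_params_reproducible_from_truth_events(self):
        spec = GaitSpec(bout_duration_s=10.0)
        _, truth = simulate_gait(spec, NoiseSpec.noiseless(), "lateral", seed=0)
        cycles = pair_bilateral(truth.events_left, truth.events_right)
        recomputed = temporal_params(
            cycles,
            subject=truth.temporal.subject.iloc[0],
            condition=truth.temporal.condition.iloc[0],
            view=truth.temporal.view.iloc[0],
        )
        cols = ["side", "cycle", "stride_time", "step_time", "stance_time",
                "swing_time", "double_support_time", "cadence"]
        a = truth.temporal[cols].reset_index(drop=True)
        b = recomputed[cols].reset_index(drop=True)
        assert a.equals(b)

    def test_truth_spatial_consistent(self):
        spec = GaitSpec(bout_duration_s=10.0)
        _, truth = simulate_gait(spec, NoiseSpec.noiseless(), "lateral", seed=0)
        np.testing.assert_allclose(truth.spatial.step_length, spec.step_length)
        np.testing.assert_allclose(
            truth.spatial.gait_speed * truth.spatial.step_time,
            truth.spatial.step_length,
            rtol=1e-12,
        )

    def test_toe_off_at_stance_fraction(self):
        spec = GaitSpec(stride_time=1.0, stance_fraction=0.64, bout_duration_s=8.0)
        _, truth = simulate_gait(spec, NoiseSpec.noiseless(), "lateral", seed=0)
        frac = (truth.events_left.toe_offs[0] % 1.0)
        assert frac == pytest.approx(0.64, abs=1e-9)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        spec = GaitSpec(bout_duration_s=6.0)
        t1, _ = simulate_gait(spec, NoiseSpec(), "lateral", seed=31)
        t2, _ = simulate_gait(spec, NoiseSpec(), "lateral", seed=31)
        assert t1.equals(t2)

    def test_different_seed_differs(self):
        spec = GaitSpec(bout_duration_s=6.0)
        t1, _ = simulate_gait(spec, NoiseSpec(), "lateral", seed=31)
        t2, _ = simulate_gait(spec, NoiseSpec(), "lateral", seed=32)
        assert not t1.equals(t2)

    def test_cohort_deterministic(self):
        c1 = simulate_cohort(n_subjects=2, seed=5, noise=NoiseSpec())
        c2 = simulate_cohort(n_subjects=2, seed=5, noise=NoiseSpec())
        for r1, r2 in zip(c1, c2):
            assert r1["candidate"].equals(r2["candidate"])
            assert r1["reference"].equals(r2["reference"])


class TestNoiselessEndToEnd:
    def test_candidate_pipeline_matches_truth(self):
        spec = GaitSpec(bout_duration_s=15.0)
        traj, truth = simulate_gait(spec, NoiseSpec.noiseless(), "lateral", seed=8)
        res = analyze_trajectory(traj, RunConfig(), preprocessed=True)
        tol = 1.0 / traj.frame_rate + 1e-9
        for param in ("stride_time", "step_time", "stance_time", "swing_time"):
            measured = res["temporal"][param].dropna().mean()
            expected = truth.temporal[param].dropna().mean()
            assert abs(measured - expected) <= tol, param
        step = res["spatial"].step_length.mean()
        assert abs(step - spec.step_length) / spec.step_length < 0.01


class TestCohort:
    def test_cohort_mean_stride_within_three_se(self):
        cohort = simulate_cohort(n_subjects=24, seed=3, noise=NoiseSpec.noiseless())
        strides = np.array([rec["spec"].stride_time for rec in cohort])
        se = 0.1 / np.sqrt(24)
        assert abs(strides.mean() - 1.1) < 3 * se

    def test_reference_and_candidate_share_clock(self):
        cohort = simulate_cohort(n_subjects=1, seed=4, noise=NoiseSpec.noiseless())
        rec = cohort[0]
        assert rec["reference"].frame_rate == 240.0
        assert rec["candidate"].frame_rate == 30.0
        # same underlying motion: truth events apply to both
        assert rec["reference"].duration_s == pytest.approx(
            rec["candidate"].duration_s, abs=0.01
        )

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(n_subjects=0)
        with pytest.raises(ValueError):
            simulate_cohort(n_subjects=2, stride_time_sd=-0.1)


class TestNoiseAndOcclusion:
    def test_hyperextension_error_names_frame(self):
        spec = GaitSpec(step_length=0.9, bout_duration_s=4.0)
        with pytest.raises(ValueError, match="frame"):
            simulate_gait(spec, NoiseSpec.noiseless(), "lateral", seed=0)

    def test_max_step_length_is_reachable_bound(self):
        spec = GaitSpec(bout_duration_s=4.0)
        limit = max_step_length(spec)
        ok = GaitSpec(step_length=0.98 * limit, bout_duration_s=4.0)
        simulate_gait(ok, NoiseSpec.noiseless(), "lateral", seed=0)  # no error
        too_far = GaitSpec(step_length=1.05 * limit, bout_duration_s=4.0)
        with pytest.raises(ValueError):
            simulate_gait(too_far, NoiseSpec.noiseless(), "lateral", seed=0)

    def test_far_side_visibility_dropout(self):
        spec = GaitSpec(bout_duration_s=20.0)
        traj, _ = simulate_gait(spec, NoiseSpec(), "lateral", seed=6)
        profile = VISIBILITY_PROFILES[("treadmill", "lateral")]
        far = traj.valid_mask("right_knee").mean()
        near = traj.valid_mask("left_knee").mean()
        assert far < 0.6 < near  # far knee mostly occluded, near knee mostly seen
        assert profile["right_knee"] == pytest.approx(0.2738)

    def test_jitter_scale(self):
        spec = GaitSpec(bout_duration_s=10.0)
        clean, _ = simulate_gait(spec, NoiseSpec.noiseless(), "lateral", seed=12)
        noisy, _ = simulate_gait(
            spec,
            NoiseSpec(jitter_sd_px=2.0, spike_rate=0.0, visibility_profile={},
                      visibility_ar_sd=0.0),
            "lateral",
            seed=12,
        )
        resid = noisy.positions["left_hip"] - clean.positions["left_hip"]
        assert 1.6 < resid.std() < 2.4

    def test_mocap_view_noiseless_millimetres(self):
        spec = GaitSpec(bout_duration_s=5.0)
        traj, _ = simulate_gait(spec, NoiseSpec(), "mocap3d", seed=1)
        assert traj.frame_rate == 240.0
        assert traj.ndim == 3
        # hip height comes out in millimetres
        hip_z = traj.positions["left_hip"][:, 1]
        assert 850.0 < hip_z.mean() < 1000.0
        assert all(traj.visibility[n].min() == 1.0 for n in traj.landmarks())
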
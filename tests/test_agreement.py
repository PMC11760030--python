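"""Method-comparison statistics against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitkit import (
    agreement_report,
    bland_altman,
    fit_identity_regression,
    mae,
    match_cycles,
)
from gaitkit.gait_events import GaitEvents


class TestMatchCycles:
    def test_identical_lists_identity(self):
        ev = GaitEvents("left", [0.0, 1.0, 2.0], [])
        assert match_cycles(ev, ev) == [(0, 0), (1, 1), (2, 2)]

    def test_uniform_shift_within_tolerance(self):
        ref = GaitEvents("left", [0.0, 1.0, 2.0], [])
        cand = GaitEvents("left", [0.1, 1.1, 2.1], [])
        assert match_cycles(ref, cand, tol_s=0.25) == [(0, 0), (1, 1), (2, 2)]

    def test_missing_candidate_strike_leaves_others_paired(self):
        ref = GaitEvents("left", [0.0, 1.0, 2.0, 3.0], [])
        cand = GaitEvents("left", [0.0, 2.0, 3.0], [])
        pairs = match_cycles(ref, cand)
        assert (1, None) not in pairs
        assert pairs == [(0, 0), (2, 1), (3, 2)]

    def test_matching_is_one_to_one(self):
        ref = GaitEvents("left", [0.0, 0.2], [])
        cand = GaitEvents("left", [0.1], [])
        pairs = match_cycles(ref, cand, tol_s=0.25)
        assert len(pairs) == 1

    def test_no_match_is_error(self):
        ref = GaitEvents("left", [0.0], [])
        cand = GaitEvents("left", [5.0], [])
        with pytest.raises(ValueError):
            match_cycles(ref, cand)


class TestMae:
    def test_identical_pairs_zero(self):
        m, sd = mae([1.0, 2.0], [1.0, 2.0])
        assert m == 0.0 and sd == 0.0

    def test_worked_example(self):
        m, _ = mae([1.0, 2.0, 3.0], [2.0, 2.0, 5.0])
        assert m == pytest.approx(1.0)

    def test_half_normal_oracle(self):
        # |d| for d ~ N(0, σ²) has mean σ·√(2/π)
        rng = np.random.default_rng(123)
        sigma = 0.02
        ref = np.zeros(1000)
        cand = rng.normal(0.0, sigma, 1000)
        m, _ = mae(ref, cand)
        expected = sigma * np.sqrt(2.0 / np.pi)
        assert abs(m - expected) / expected < 0.10


class TestBlandAltman:
    def test_identical_pairs(self):
        bias, lo, hi = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert bias == lo == hi == 0.0

    def test_alternating_differences_closed_form(self):
        ref = np.zeros(4)
        cand = np.array([1.0, -1.0, 1.0, -1.0])
        bias, lo, hi = bland_altman(ref, cand)
        sd = np.std(cand, ddof=1)  # = 2/√3 ≈ 1.1547
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * sd)
        assert hi == pytest.approx(2.2632, abs=5e-4)
        assert lo == pytest.approx(-hi)

    def test_constant_offset_zero_width(self):
        bias, lo, hi = bland_altman([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])
        assert bias == pytest.approx(0.5)
        assert lo == pytest.approx(0.5) and hi == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        diffs=st.lists(st.floats(-10, 10), min_size=2, max_size=40),
        base=st.floats(-5, 5),
    )
    def test_limits_bracket_bias_with_exact_width(self, diffs, base):
        ref = np.full(len(diffs), base)
        cand = ref + np.array(diffs)
        bias, lo, hi = bland_altman(ref, cand)
        assert lo <= bias + 1e-12 and bias <= hi + 1e-12
        sd = np.std(np.array(diffs), ddof=1)
        assert (hi - lo) == pytest.approx(2 * 1.96 * sd, abs=1e-9)


class TestRegression:
    def test_identity(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r = fit_identity_regression(ref, ref)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0)
        assert r == pytest.approx(1.0)

    def test_double_slope(self):
        ref = np.array([1.0, 2.0, 3.0])
        slope, _, r = fit_identity_regression(ref, 2 * ref)
        assert slope == pytest.approx(2.0) and r == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        ref = rng.uniform(0.5, 1.5, 200)
        cand = 0.95 * ref + 0.03 + rng.normal(0, 0.05, 200)
        slope, intercept, _ = fit_identity_regression(ref, cand)
        X = np.column_stack([ref, np.ones_like(ref)])
        beta = np.linalg.solve(X.T @ X, X.T @ cand)
        assert slope == pytest.approx(beta[0], abs=1e-9)
        assert intercept == pytest.approx(beta[1], abs=1e-9)

    def test_scale_equivariance_of_slope_and_r(self):
        rng = np.random.default_rng(8)
        ref = rng.uniform(1, 2, 50)
        cand = ref + rng.normal(0, 0.1, 50)
        s1, _, r1 = fit_identity_regression(ref, cand)
        s2, _, r2 = fit_identity_regression(10 * ref, 10 * cand)
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_identity_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _param_table(subjects, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s, stride in subjects.items():
        for k in range(10):
            rows.append(
                {
                    "subject": s,
                    "condition": "treadmill",
                    "view": "lateral",
                    "side": "left" if k % 2 == 0 else "right",
                    "cycle": k // 2,
                    "hs_time": 1.1 * k,
                    "stride_time": stride + rng.normal(0, noise),
                }
            )
    return pd.DataFrame(rows)


class TestAgreementReport:
    def test_candidate_equals_reference_all_zero(self):
        ref = _param_table({"a": 1.0, "b": 1.2})
        rep = agreement_report(ref, ref.copy(), mode="all_step")
        row = rep[rep.parameter == "stride_time"].iloc[0]
        assert row.mae == 0.0
        assert row.slope == pytest.approx(1.0)
        assert row.loa_low == row.loa_high == 0.0

    def test_participants_mean_not_larger_than_all_step(self):
        ref = _param_table({"a": 1.0, "b": 1.2, "c": 0.9})
        cand = _param_table({"a": 1.0, "b": 1.2, "c": 0.9}, noise=0.03, seed=5)
        pm = agreement_report(ref, cand, mode="participants_mean")
        al = agreement_report(ref, cand, mode="all_step")
        assert (
            pm[pm.parameter == "stride_time"].mae.iloc[0]
            <= al[al.parameter == "stride_time"].mae.iloc[0]
        )

    def test_no_common_subjects_rejected(self):
        ref = _param_table({"a": 1.0})
        cand = _param_table({"z": 1.0})
        with pytest.raises(ValueError, match="common subjects"):
            agreement_report(ref, cand)
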
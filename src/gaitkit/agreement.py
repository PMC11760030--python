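"""Method-comparison statistics between a candidate and a reference system.

The candidate here is video-based pose estimation and the reference a
marker-based capture system, but the statistics are generic: matched
per-cycle measurements are compared by mean absolute error (MAE ± SD of
the absolute differences), ordinary least-squares regression of candidate
on reference (with Pearson r reported alongside the slope, since
published comparison tables are ambiguous between the two), and
Bland–Altman analysis — bias = mean(candidate − reference) with 95%
limits of agreement at bias ± 1.96 × sample SD of the differences.

Two aggregation modes mirror common reporting practice: averaging each
subject's cycles first (``participants_mean``) or pooling every cycle
(``all_step``).  Subject-level averaging removes within-subject cycle
noise, so its errors are systematically the smaller of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gait_events import GaitEvents

#: default cycle-matching tolerance (s) — below half the minimum
#: physiological stride period, so matches cannot skip a cycle
DEFAULT_MATCH_TOL_S = 0.25


@dataclass
class AgreementStats:
    """Agreement summary for one parameter under one aggregation mode."""

    parameter: str
    mode: str
    n: int
    mae: float
    mae_sd: float
    slope: float
    intercept: float
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float


def match_cycles(
    ref_events: GaitEvents,
    cand_events: GaitEvents,
    tol_s: float = DEFAULT_MATCH_TOL_S,
) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest-neighbour matching of heel strikes.

    Both event lists must share a synchronised clock.  Candidate strikes
    farther than ``tol_s`` from every remaining reference strike stay
    unmatched and are dropped.
    """
    ref = ref_events.heel_strikes
    cand = cand_events.heel_strikes
    if ref.size == 0 or cand.size == 0:
        raise ValueError("both event lists must be non-empty")
    dist = np.abs(ref[:, None] - cand[None, :])
    order = np.argsort(dist, axis=None)
    used_r: set[int] = set()
    used_c: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), cand.size)
        if dist[i, j] > tol_s:
            break
        if i in used_r or j in used_c:
            continue
        pairs.append((i, j))
        used_r.add(i)
        used_c.add(j)
    if not pairs:
        raise ValueError(f"no heel strikes match within {tol_s} s")
    return sorted(pairs)


def _paired(ref, cand) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float)
    cand = np.asarray(cand, dtype=float)
    if ref.shape != cand.shape:
        raise ValueError("reference and candidate must have equal length")
    ok = np.isfinite(ref) & np.isfinite(cand)
    return ref[ok], cand[ok]


def mae(ref, cand) -> tuple[float, float]:
    """Mean and SD of absolute candidate−reference differences."""
    ref, cand = _paired(ref, cand)
    if ref.size < 1:
        raise ValueError("at least one finite pair is required")
    abs_diff = np.abs(cand - ref)
    sd = float(np.std(abs_diff, ddof=1)) if abs_diff.size > 1 else 0.0
    return float(np.mean(abs_diff)), sd


def bland_altman(ref, cand) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of candidate − reference.

    Returns ``(bias, loa_low, loa_high)`` with the limits at
    bias ± 1.96 × sample (n−1) SD of the differences.
    """
    ref, cand = _paired(ref, cand)
    if ref.size < 2:
        raise ValueError("Bland–Altman needs at least 2 pairs")
    diff = cand - ref
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def fit_identity_regression(ref, cand) -> tuple[float, float, float]:
    """OLS fit candidate = slope·reference + intercept, plus Pearson r."""
    ref, cand = _paired(ref, cand)
    if ref.size < 3:
        raise ValueError("regression needs at least 3 pairs")
    if np.ptp(ref) == 0:
        raise ValueError("reference values have zero variance")
    res = stats.linregress(ref, cand)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def _match_tables(
    ref: pd.DataFrame, cand: pd.DataFrame, tol_s: float
) -> pd.DataFrame:
    """Pair per-cycle rows of two parameter tables by strike time."""
    common = sorted(set(ref["subject"]) & set(cand["subject"]))
    if not common:
        raise ValueError("no common subjects between the two tables")
    merged = []
    for subject in common:
        for side in sorted(set(ref["side"])):
            r = ref[(ref["subject"] == subject) & (ref["side"] == side)]
            c = cand[(cand["subject"] == subject) & (cand["side"] == side)]
            if r.empty or c.empty:
                continue
            rt = r["hs_time"].to_numpy()
            ct = c["hs_time"].to_numpy()
            dist = np.abs(rt[:, None] - ct[None, :])
            order = np.argsort(dist, axis=None)
            used_r: set[int] = set()
            used_c: set[int] = set()
            for flat in order:
                i, j = divmod(int(flat), ct.size)
                if dist[i, j] > tol_s:
                    break
                if i in used_r or j in used_c:
                    continue
                used_r.add(i)
                used_c.add(j)
                merged.append(
                    pd.concat(
                        [
                            r.iloc[i].add_suffix("_ref"),
                            c.iloc[j].add_suffix("_cand"),
                        ]
                    )
                )
    if not merged:
        raise ValueError("no cycles matched between reference and candidate")
    return pd.DataFrame(merged).reset_index(drop=True)


def agreement_report(
    ref_params: pd.DataFrame,
    cand_params: pd.DataFrame,
    mode: str = "participants_mean",
    parameters: list[str] | None = None,
    tol_s: float = DEFAULT_MATCH_TOL_S,
) -> pd.DataFrame:
    """Full agreement table: one row per parameter under one mode.

    Cycles are matched one-to-one within each subject and side by heel
    strike time (``hs_time`` column, tolerance ``tol_s``), aggregated per
    ``mode``, and summarised by MAE, OLS slope/intercept, Pearson r, and
    Bland–Altman bias and limits.  The difference direction is
    candidate − reference throughout.
    """
    if mode not in ("participants_mean", "all_step"):
        raise ValueError("mode must be 'participants_mean' or 'all_step'")
    if parameters is None:
        skip = {"cycle", "hs_time"}
        parameters = [
            c
            for c in ref_params.columns
            if c in cand_params.columns
            and c not in skip
            and pd.api.types.is_numeric_dtype(ref_params[c])
        ]
    matched = _match_tables(ref_params, cand_params, tol_s)
    rows = []
    for param in parameters:
        pairs = matched[["subject_ref", f"{param}_ref", f"{param}_cand"]].dropna()
        if mode == "participants_mean":
            agg = pairs.groupby("subject_ref").mean()
            ref_v = agg[f"{param}_ref"].to_numpy()
            cand_v = agg[f"{param}_cand"].to_numpy()
        else:
            ref_v = pairs[f"{param}_ref"].to_numpy()
            cand_v = pairs[f"{param}_cand"].to_numpy()
        if ref_v.size < 2:
            continue
        m, m_sd = mae(ref_v, cand_v)
        bias, lo, hi = bland_altman(ref_v, cand_v)
        if ref_v.size >= 3 and np.ptp(ref_v) > 0:
            slope, intercept, r = fit_identity_regression(ref_v, cand_v)
        else:
            slope = intercept = r = np.nan
        rows.append(
            AgreementStats(
                parameter=param,
                mode=mode,
                n=int(ref_v.size),
                mae=m,
                mae_sd=m_sd,
                slope=slope,
                intercept=intercept,
                pearson_r=r,
                bias=bias,
                loa_low=lo,
                loa_high=hi,
            ).__dict__
        )
    if not rows:
        raise ValueError("no parameter had enough matched pairs")
    return pd.DataFrame(rows)
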
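"""Temporospatial gait parameters from validated gait events.

Temporal parameters are pure event arithmetic: for a cycle of one side
running from heel strike ``HS(k)`` to ``HS(k+1)`` with the contralateral
strike ``HS_c`` and toe-offs ``TO`` / ``TO_c`` inside it,

* stride time  = ``HS(k+1) − HS(k)``
* step time    = ``HS_c − HS(k)``
* stance time  = ``TO − HS(k)``
* swing time   = stride − stance (exact by construction)
* double support = ``(TO_c − HS(k)) + (TO − HS_c)`` — the two
  bilateral-contact intervals within the stride
* cadence      = ``60 / step time`` steps/min, defined per cycle so that
  stride-by-stride analysis remains possible.

Spatial parameters need positions: step length is the progression-axis
separation of the two heels at the striking instant, converted to metres
by the pixel calibration (lateral video) or the capture system's
millimetre scale.  This instantaneous-separation convention is exact
overground (the trailing heel is planted at its own strike position) and
equals belt speed × step time on a treadmill, so one definition serves
both.  Gait speed is step length divided by step time.  A near-frontal
camera looks along the progression axis, so spatial parameters are
undefined for that view.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gait_events import Cycle
from .trajectory import ScaleCalibration, TrajectorySet

TEMPORAL_COLUMNS = (
    "stride_time",
    "step_time",
    "stance_time",
    "swing_time",
    "double_support_time",
    "cadence",
)
SPATIAL_COLUMNS = ("step_length", "gait_speed")
_ID_COLUMNS = ["subject", "condition", "view", "side", "cycle"]


def temporal_params(
    cycles: list[Cycle],
    subject: str = "s0",
    condition: str = "treadmill",
    view: str = "lateral",
) -> pd.DataFrame:
    """Per-cycle temporal parameters from a validated bilateral cycle list.

    A cycle whose toe-off information is missing keeps its stride and
    step times; stance, swing, and double support are NaN for that cycle.
    """
    if not cycles:
        raise ValueError("at least one valid cycle is required")
    rows = []
    for c in cycles:
        stride = c.hs_next - c.hs
        step = c.hs_contra - c.hs if c.hs_contra is not None else np.nan
        stance = c.to_ipsi - c.hs if c.to_ipsi is not None else np.nan
        swing = stride - stance
        if c.to_contra is not None and c.hs_contra is not None and c.to_ipsi is not None:
            ds = (c.to_contra - c.hs) + (c.to_ipsi - c.hs_contra)
        else:
            ds = np.nan
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "view": view,
                "side": c.side,
                "cycle": c.index,
                "hs_time": c.hs,
                "stride_time": stride,
                "step_time": step,
                "stance_time": stance,
                "swing_time": swing,
                "double_support_time": ds,
                "cadence": 60.0 / step if np.isfinite(step) and step > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _progression_m(
    traj: TrajectorySet, name: str, calib: ScaleCalibration | None
) -> np.ndarray:
    x = traj.positions[name][:, 0]
    if traj.view == "mocap3d":
        return x / 1000.0  # anterior axis in millimetres
    if calib is None:
        raise ValueError("pixel-to-metre calibration required for video data")
    return x / calib.pixels_per_meter


def _refine_strike_time(
    traj: TrajectorySet, heel_prog: np.ndarray, t_event: float
) -> float:
    """Sub-frame strike instant from the parabola vertex of the striking
    heel's progression relative to the hip centre around the event sample."""
    if not (traj.has("left_hip") and traj.has("right_hip")):
        return t_event
    hip = 0.5 * (
        _hip_prog(traj, "left_hip") + _hip_prog(traj, "right_hip")
    )
    rel = heel_prog - hip
    k = int(round(t_event * traj.frame_rate))
    if k < 1 or k > rel.size - 2 or not np.all(np.isfinite(rel[k - 1 : k + 2])):
        return t_event
    y0, y1, y2 = rel[k - 1], rel[k], rel[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return t_event
    dk = 0.5 * (y0 - y2) / denom
    if abs(dk) > 1.0:
        return t_event
    return (k + dk) / traj.frame_rate


def _hip_prog(traj: TrajectorySet, name: str) -> np.ndarray:
    return traj.positions[name][:, 0]


def spatial_params(
    traj: TrajectorySet,
    cycles: list[Cycle],
    calib: ScaleCalibration | None = None,
    foot_landmark: str = "heel",
    subject: str = "s0",
    condition: str = "treadmill",
) -> pd.DataFrame:
    """Per-step step length and gait speed.

    The step measured for a cycle of side ``s`` is the one completed by
    the contralateral foot's strike inside that cycle, matching the
    cycle's step time; records are labelled with the cycle's side and
    index.  Steps with (near-)zero heel separation are degenerate and
    excluded, flagged in the result's ``attrs['excluded']``.
    """
    if traj.view == "near_frontal":
        raise ValueError(
            "spatial parameters undefined for near-frontal view: progression "
            "runs along the optical axis, so no image axis measures it"
        )
    if not cycles:
        raise ValueError("at least one valid cycle is required")
    prog = {
        side: _progression_m(traj, f"{side}_{foot_landmark}", calib)
        for side in ("left", "right")
        if traj.has(f"{side}_{foot_landmark}")
    }
    if len(prog) < 2:
        raise ValueError(f"both {foot_landmark} landmarks are required")
    t = traj.times()
    rows, excluded = [], []
    for c in cycles:
        if c.hs_contra is None:
            continue
        contra = "right" if c.side == "left" else "left"
        # sample both heels at the strike instant (linear between frames).
        # Event times are quantised to the frame grid while the trailing
        # heel moves at walking speed, so the instant is first refined to
        # sub-frame precision using the striking heel's hip-relative
        # progression, which is extremal (flat) at the true strike.
        tc = float(np.clip(c.hs_contra, t[0], t[-1]))
        tc = _refine_strike_time(traj, prog[contra], tc)
        tc = float(np.clip(tc, t[0], t[-1]))
        sep = abs(
            np.interp(tc, t, prog[contra]) - np.interp(tc, t, prog[c.side])
        )
        step_time = c.hs_contra - c.hs
        if not np.isfinite(sep) or sep < 1e-6 or step_time <= 0:
            excluded.append((c.side, c.index))
            continue
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "view": traj.view,
                "side": c.side,
                "cycle": c.index,
                "hs_time": c.hs,
                "step_length": sep,
                "step_time": step_time,
                "gait_speed": sep / step_time,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["excluded"] = excluded
    return df


def summarize_subject(params: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Aggregate per-cycle records for agreement analysis.

    ``participants_mean`` averages every numeric parameter across a
    subject's cycles (one row per subject per side-agnostic mean);
    ``all_step`` passes the records through untouched.
    """
    if params.empty:
        raise ValueError("no parameter records to summarise")
    if mode == "all_step":
        return params.copy()
    if mode != "participants_mean":
        raise ValueError("mode must be 'participants_mean' or 'all_step'")
    value_cols = [
        c
        for c in params.columns
        if c not in _ID_COLUMNS + ["hs_time"]
        and pd.api.types.is_numeric_dtype(params[c])
    ]
    grouped = params.groupby("subject", as_index=False)[value_cols].mean()
    for col in ("condition", "view"):
        if col in params.columns:
            first = params.groupby("subject")[col].first().reset_index(drop=True)
            grouped[col] = first
    return grouped


def params_to_long(params: pd.DataFrame) -> pd.DataFrame:
    """Wide per-cycle table → long ``…,parameter,value`` export form."""
    id_cols = [c for c in _ID_COLUMNS if c in params.columns]
    value_cols = [
        c
        for c in params.columns
        if c not in id_cols + ["hs_time"] and pd.api.types.is_numeric_dtype(params[c])
    ]
    return params.melt(
        id_vars=id_cols, value_vars=value_cols, var_name="parameter", value_name="value"
    )
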
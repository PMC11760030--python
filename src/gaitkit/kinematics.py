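"""Sagittal-plane joint angles from three-landmark triplets.

Each joint angle is the interior angle at the middle landmark of a
triplet — shoulder–hip–knee (hip), hip–knee–ankle (knee), and
knee–ankle–foot (ankle, with the toe as the default foot point since it
defines the conventional foot-segment direction) — mapped onto a signed
flexion convention:

* hip and knee: flexion positive, full extension 0° (``180° − interior``
  with the sign taken from the triplet's orientation and the subject's
  facing direction);
* ankle: dorsiflexion positive, neutral (shank ⟂ foot) 0°
  (``90° − interior``).

2D video angles are computed in the image plane; 3D capture angles are
projected onto the sagittal plane (progression × vertical axes) first.
The interior angle itself is invariant under rotation, translation,
uniform scaling, and swapping the outer points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gait_events import GaitEvents, _facing_sign
from .trajectory import TrajectorySet

JOINT_TRIPLETS = {
    "hip": ("shoulder", "hip", "knee"),
    "knee": ("hip", "knee", "ankle"),
    "ankle": ("knee", "ankle", "foot"),
}


@dataclass
class JointAngleSeries:
    """Signed sagittal angle per frame for one joint of one side."""

    joint: str
    side: str
    angles_deg: np.ndarray
    frame_rate: float
    convention: str = "flexion_positive"

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        finite = self.angles_deg[np.isfinite(self.angles_deg)]
        if finite.size and np.any(np.abs(finite) > 180.0):
            raise ValueError("joint angles must lie within ±180°")


@dataclass
class RangeOfMotion:
    """Per-cycle max−min of a joint angle, summarised across cycles."""

    joint: str
    side: str
    per_cycle_deg: np.ndarray
    mean_deg: float
    sd_deg: float


def three_point_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Interior angle at vertex ``b`` between rays b→a and b→c, degrees.

    Accepts single points or stacked arrays of shape ``(n, dim)``.
    Samples where either ray degenerates to zero length are undefined and
    returned as NaN.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    c = np.atleast_2d(np.asarray(c, dtype=float))
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    dot = np.einsum("...i,...i->...", u, v)
    if u.shape[-1] == 2:
        cross_mag = np.abs(u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0])
    else:
        cross_mag = np.linalg.norm(np.cross(u, v), axis=-1)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(cross_mag, dot))
        ang = np.where((nu == 0) | (nv == 0), np.nan, ang)
    return ang if ang.size > 1 else float(ang[0])


def _cross_z(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    u = a - b
    v = c - b
    return u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]


def joint_angle_series(
    traj: TrajectorySet,
    joint: str,
    side: str,
    foot_landmark: str = "foot_index",
    direction: float | None = None,
) -> JointAngleSeries:
    """Per-frame signed sagittal angle for one joint of one side.

    ``foot_landmark`` selects the foot point of the ankle triplet
    (``foot_index`` i.e. the toe, or ``heel``).  ``direction`` overrides
    the automatic facing estimate used to sign flexion.
    """
    if joint not in JOINT_TRIPLETS:
        raise ValueError(f"joint must be one of {sorted(JOINT_TRIPLETS)}")
    names = []
    for point in JOINT_TRIPLETS[joint]:
        point = foot_landmark if point == "foot" else point
        name = f"{side}_{point}"
        if not traj.has(name):
            raise ValueError(f"landmark {name!r} missing for {joint} angle")
        names.append(name)
    # sagittal plane: image plane for video (y down), progression ×
    # vertical for 3D capture (y up)
    pts = [traj.positions[n][:, :2] for n in names]
    a, b, c = pts
    interior = np.atleast_1d(three_point_angle(a, b, c))
    facing = direction if direction is not None else _facing_sign(traj)
    y_up = 1.0 if traj.view == "mocap3d" else -1.0
    if joint == "ankle":
        angles = 90.0 - interior  # dorsiflexion positive
    else:
        orient = np.sign(_cross_z(a, b, c)) * facing * y_up
        if joint == "hip":
            orient = -orient  # hip flexes anteriorly, knee posteriorly
        angles = (180.0 - interior) * np.where(orient == 0, 1.0, orient)
    return JointAngleSeries(joint, side, angles, traj.frame_rate)


def range_of_motion(
    series: JointAngleSeries, events: GaitEvents, min_valid_fraction: float = 0.5
) -> RangeOfMotion:
    """Per-cycle range (max − min) of the angle, mean ± SD across cycles.

    A cycle is the interval between consecutive ipsilateral heel strikes;
    cycles with less than ``min_valid_fraction`` of their samples present
    (occlusion gaps) are skipped.
    """
    hs = events.heel_strikes
    if hs.size < 2:
        raise ValueError("range of motion needs at least one complete cycle")
    fr = series.frame_rate
    roms = []
    for t0, t1 in zip(hs[:-1], hs[1:]):
        i0, i1 = int(round(t0 * fr)), int(round(t1 * fr))
        chunk = series.angles_deg[max(i0, 0) : min(i1, series.angles_deg.size)]
        if chunk.size == 0:
            continue
        valid = np.isfinite(chunk)
        if valid.mean() < min_valid_fraction:
            continue
        roms.append(float(np.nanmax(chunk) - np.nanmin(chunk)))
    if not roms:
        raise ValueError("no cycle with enough valid angle samples")
    roms = np.asarray(roms)
    return RangeOfMotion(
        joint=series.joint,
        side=series.side,
        per_cycle_deg=roms,
        mean_deg=float(np.mean(roms)),
        sd_deg=float(np.std(roms, ddof=1)) if roms.size > 1 else 0.0,
    )


def angle_agreement(
    series_a: JointAngleSeries | np.ndarray, series_b: JointAngleSeries | np.ndarray
) -> tuple[float, float]:
    """MAE (degrees) and Pearson r between two synchronised angle series.

    The series must already share length and frame rate (resample or trim
    first); samples missing in either series are excluded pairwise.
    """
    a = series_a.angles_deg if isinstance(series_a, JointAngleSeries) else np.asarray(series_a, float)
    b = series_b.angles_deg if isinstance(series_b, JointAngleSeries) else np.asarray(series_b, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 overlapping valid samples")
    mae = float(np.mean(np.abs(a[ok] - b[ok])))
    r = float(stats.pearsonr(a[ok], b[ok]).statistic)
    return mae, r


def normalize_cycles(
    series: JointAngleSeries, events: GaitEvents, n_points: int = 101
) -> np.ndarray:
    """Resample each gait cycle of an angle trace onto 0–100% of the cycle.

    Returns an ``(n_cycles, n_points)`` array for ensemble-average
    plotting; cycles with missing samples are linearly bridged where
    possible and rows that stay incomplete are dropped.
    """
    hs = events.heel_strikes
    fr = series.frame_rate
    rows = []
    for t0, t1 in zip(hs[:-1], hs[1:]):
        i0, i1 = int(round(t0 * fr)), int(round(t1 * fr))
        chunk = series.angles_deg[max(i0, 0) : min(i1, series.angles_deg.size)]
        valid = np.isfinite(chunk)
        if chunk.size < 4 or valid.mean() < 0.5 or not valid.any():
            continue
        x = np.flatnonzero(valid)
        filled = np.interp(np.arange(chunk.size), x, chunk[x])
        phase = np.linspace(0.0, 1.0, chunk.size)
        rows.append(np.interp(np.linspace(0, 1, n_points), phase, filled))
    return np.asarray(rows) if rows else np.empty((0, n_points))
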
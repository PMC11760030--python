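"""Readers and writers for keypoint and marker trajectory files.

Two plain-text dialects are supported for 2D keypoints:

* CSV with header ``frame,landmark,x,y,visibility`` — one row per
  (frame, landmark) sample;
* JSON — a list of frames, each a list of ``{"name", "x", "y",
  "visibility"}`` landmark records.

3D motion-capture exports are long-form CSV with header
``frame,marker,x,y,z`` (millimetres); a marker-name → landmark mapping
supplied by the caller bridges whatever marker set the capture software
used to the twelve body points gait analysis consumes.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .landmarks import BodyPoint, Side, canonical_name, landmark_name, resolve
from .trajectory import ScaleCalibration, TrajectorySet

REQUIRED_BODY_POINTS = (
    BodyPoint.SHOULDER,
    BodyPoint.HIP,
    BodyPoint.KNEE,
    BodyPoint.ANKLE,
    BodyPoint.HEEL,
    BodyPoint.TOE,
)


def _assemble(
    frames: np.ndarray,
    records: pd.DataFrame,
    frame_rate: float,
    view: str,
    coords: tuple[str, ...],
    visibility_floor: float,
    **kwargs,
) -> TrajectorySet:
    """Pivot long-form (frame, landmark, coords...) records into arrays."""
    n = frames.size
    pos_index = {int(f): i for i, f in enumerate(frames)}
    positions: dict[str, np.ndarray] = {}
    visibility: dict[str, np.ndarray] = {}
    for name, group in records.groupby("landmark", sort=True):
        pos = np.full((n, len(coords)), np.nan)
        vis = np.zeros(n)
        rows = [pos_index[int(f)] for f in group["frame"].to_numpy()]
        pos[rows] = group[list(coords)].to_numpy(dtype=float)
        if "visibility" in group:
            vis[rows] = group["visibility"].to_numpy(dtype=float)
        else:
            vis[rows] = 1.0
        # drop samples under the visibility floor, and samples with NaN coords
        gap = np.any(np.isnan(pos), axis=1) | (vis < visibility_floor)
        pos[gap] = np.nan
        vis[gap] = np.minimum(vis[gap], np.nextafter(1.0, 0.0))
        positions[str(name)] = pos
        visibility[str(name)] = np.clip(vis, 0.0, 1.0)
    return TrajectorySet(
        frames=frames,
        positions=positions,
        visibility=visibility,
        frame_rate=frame_rate,
        view=view,
        **kwargs,
    )


def _check_duplicates(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=["frame", "landmark"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate sample for frame {int(row['frame'])}, "
            f"landmark {row['landmark']!r}"
        )


def read_keypoints(
    path: str | Path,
    frame_rate: float,
    view: str,
    visibility_floor: float = 0.0,
    **kwargs,
) -> TrajectorySet:
    """Read 2D keypoints from CSV or JSON into a :class:`TrajectorySet`.

    ``visibility_floor`` converts samples whose reported visibility is
    below the floor into gaps (default 0: keep everything).  Unknown
    landmark names are preserved and recorded under ``meta['unknown']``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = _json_to_long(path)
    else:
        df = pd.read_csv(path)
        missing = {"frame", "landmark", "x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"keypoint CSV missing columns: {sorted(missing)}")
        if "visibility" not in df.columns:
            df["visibility"] = 1.0
    df["landmark"] = df["landmark"].map(canonical_name)
    _check_duplicates(df)
    frame_vals = df["frame"].to_numpy(dtype=int)
    frames = np.unique(frame_vals)
    # file row order may be arbitrary; np.unique normalises to increasing,
    # but a frame column that jumps backwards *within* one landmark's rows
    # is normalised too — only duplicates are treated as errors.
    traj = _assemble(
        frames, df, frame_rate, view, ("x", "y"), visibility_floor, **kwargs
    )
    unknown = sorted(
        {name for name in traj.positions if not resolve(name).known}
    )
    if unknown:
        traj.meta["unknown"] = unknown
    return traj


def _json_to_long(path: Path) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    rows = []
    for k, frame in enumerate(payload):
        for rec in frame:
            rows.append(
                {
                    "frame": k,
                    "landmark": rec["name"],
                    "x": rec["x"],
                    "y": rec["y"],
                    "visibility": rec.get("visibility", 1.0),
                }
            )
    if not rows:
        raise ValueError(f"{path}: no landmark records")
    return pd.DataFrame(rows)


def write_keypoints(traj: TrajectorySet, path: str | Path) -> Path:
    """Write a 2D trajectory as CSV or JSON (chosen by file suffix)."""
    path = Path(path)
    if traj.ndim != 2:
        raise ValueError("write_keypoints handles 2D trajectories; use write_mocap_csv")
    if path.suffix.lower() == ".json":
        frames_out = []
        for i in range(traj.n_frames):
            recs = []
            for name in traj.landmarks():
                x, y = traj.positions[name][i]
                if np.isnan(x):
                    continue
                recs.append(
                    {
                        "name": name,
                        "x": float(x),
                        "y": float(y),
                        "visibility": float(traj.visibility[name][i]),
                    }
                )
            frames_out.append(recs)
        path.write_text(json.dumps(frames_out))
        return path
    rows = []
    for name in traj.landmarks():
        valid = traj.valid_mask(name)
        for i in np.flatnonzero(valid):
            rows.append(
                (
                    int(traj.frames[i]),
                    name,
                    float(traj.positions[name][i, 0]),
                    float(traj.positions[name][i, 1]),
                    float(traj.visibility[name][i]),
                )
            )
    df = pd.DataFrame(rows, columns=["frame", "landmark", "x", "y", "visibility"])
    df.sort_values(["frame", "landmark"]).to_csv(path, index=False)
    return path


def read_mocap_csv(
    path: str | Path,
    marker_map: dict[str, str],
    frame_rate: float = 240.0,
    **kwargs,
) -> TrajectorySet:
    """Read a 3D marker export (``frame,marker,x,y,z`` CSV, millimetres).

    ``marker_map`` maps the capture system's marker names onto canonical
    landmark names (``left_heel``, ``right_ankle``, ...).  All twelve
    consumed body points must be covered; unmapped markers are dropped.
    Empty coordinate cells become gaps.
    """
    df = pd.read_csv(path)
    missing = {"frame", "marker", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"mocap CSV missing columns: {sorted(missing)}")
    cmap = {k: canonical_name(v) for k, v in marker_map.items()}
    covered = set(cmap.values())
    missing_points = [
        f"{side.value} {point.value}"
        for point in REQUIRED_BODY_POINTS
        for side in (Side.LEFT, Side.RIGHT)
        if landmark_name(point, side) not in covered
    ]
    if missing_points:
        raise ValueError(f"marker_map leaves body points unmapped: {missing_points}")
    df = df[df["marker"].isin(cmap)].copy()
    df["landmark"] = df["marker"].map(cmap)
    _check_duplicates(df)
    frames = np.unique(df["frame"].to_numpy(dtype=int))
    return _assemble(
        frames, df, frame_rate, "mocap3d", ("x", "y", "z"), 0.0, **kwargs
    )


def write_mocap_csv(traj: TrajectorySet, path: str | Path) -> Path:
    """Write a 3D trajectory as ``frame,marker,x,y,z`` CSV."""
    if traj.ndim != 3:
        raise ValueError("write_mocap_csv handles 3D trajectories")
    rows = []
    for name in traj.landmarks():
        pos = traj.positions[name]
        for i in np.flatnonzero(traj.valid_mask(name)):
            rows.append((int(traj.frames[i]), name, *map(float, pos[i])))
    df = pd.DataFrame(rows, columns=["frame", "marker", "x", "y", "z"])
    df.sort_values(["frame", "marker"]).to_csv(Path(path), index=False)
    return Path(path)


def calibrate_scale(
    point_a_px: tuple[float, float],
    point_b_px: tuple[float, float],
    known_distance_m: float,
) -> ScaleCalibration:
    """Pixel-per-metre scale from two image points a known distance apart."""
    if not known_distance_m > 0:
        raise ValueError("known distance must be positive")
    ax, ay = point_a_px
    bx, by = point_b_px
    d_px = math.hypot(bx - ax, by - ay)
    if d_px == 0:
        raise ValueError("calibration points are coincident")
    return ScaleCalibration(
        point_a_px=(float(ax), float(ay)),
        point_b_px=(float(bx), float(by)),
        known_distance_m=float(known_distance_m),
        pixels_per_meter=d_px / known_distance_m,
    )
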
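"""Heel-strike and toe-off detection from keypoint trajectories.

The detector follows the coordinate-based event convention widely used
for treadmill and overground kinematic data: the progression-axis
position of the foot *relative to the pelvis* oscillates once per stride,
reaching its forward extreme at heel strike and its backward extreme at
toe-off.  Local maxima of that relative signal are therefore labelled
heel strikes and local minima toe-offs.

For a lateral camera the progression axis is the horizontal image axis;
for a near-frontal camera, where progression is along the optical axis,
the vertical image coordinate of the heel (heel strike) and the toe
(toe-off) relative to the hip centre carries the same once-per-stride
oscillation — the forward foot is nearer the camera and projects farther
from the body centre.  Events are timestamped at the peak sample, so the
expected timing error is bounded by one frame; optional parabolic
sub-frame refinement is available but off by default.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .trajectory import TrajectorySet

#: default minimum stride period (s); cadence above 200 steps/min is
#: outside the physiological range and indicates a split peak
DEFAULT_MIN_STRIDE_S = 0.6
#: peak prominence threshold, as a fraction of the signal's interquartile
#: range — scale-free and robust to baseline drift
PROMINENCE_IQR_FRACTION = 0.25


@dataclass
class GaitEvents:
    """Ordered heel-strike and toe-off times (seconds) for one side."""

    side: str
    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    source_view: str = "lateral"

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=float)
        self.toe_offs = np.asarray(self.toe_offs, dtype=float)
        for arr, label in ((self.heel_strikes, "heel_strikes"), (self.toe_offs, "toe_offs")):
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{label} must be strictly increasing")

    @property
    def n_strides(self) -> int:
        return max(self.heel_strikes.size - 1, 0)

    def shifted(self, dt: float) -> "GaitEvents":
        return GaitEvents(
            self.side, self.heel_strikes + dt, self.toe_offs + dt, self.source_view
        )


@dataclass
class Cycle:
    """One validated gait cycle: ipsilateral HS→HS with interior events."""

    side: str
    index: int
    hs: float
    hs_next: float
    hs_contra: float | None = None
    to_ipsi: float | None = None
    to_contra: float | None = None


def _facing_sign(traj: TrajectorySet) -> float:
    """+1 if the subject faces the +x axis, judged from toe−heel offsets."""
    diffs = []
    for side in ("left", "right"):
        toe, heel = f"{side}_foot_index", f"{side}_heel"
        if traj.has(toe) and traj.has(heel):
            d = traj.positions[toe][:, 0] - traj.positions[heel][:, 0]
            d = d[np.isfinite(d)]
            if d.size:
                diffs.append(np.median(d))
    if not diffs:
        return 1.0
    s = float(np.sign(np.mean(diffs)))
    return s if s != 0 else 1.0


def _approach_sign(traj: TrajectorySet) -> float:
    """+1 if a near-frontal subject approaches the camera (trunk grows)."""
    pairs = []
    for a, b in (("left_shoulder", "left_hip"), ("right_shoulder", "right_hip")):
        if traj.has(a) and traj.has(b):
            pairs.append(
                np.abs(traj.positions[a][:, 1] - traj.positions[b][:, 1])
            )
    if not pairs:
        return 1.0
    trunk = np.nanmean(pairs, axis=0)
    ok = np.isfinite(trunk)
    if ok.sum() < 2:
        return 1.0
    t = np.flatnonzero(ok)
    slope = np.polyfit(t, trunk[ok], 1)[0]
    # relative size change over the bout; a negligible trend means the
    # subject holds distance (treadmill) and faces the camera
    rel = slope * trunk.size / float(np.nanmean(trunk))
    if abs(rel) < 0.05:
        return 1.0
    return 1.0 if slope >= 0 else -1.0


def hip_center(traj: TrajectorySet) -> np.ndarray:
    for name in ("left_hip", "right_hip"):
        if not traj.has(name):
            raise ValueError(f"hip centre needs both hips; {name} missing")
    return 0.5 * (traj.positions["left_hip"] + traj.positions["right_hip"])


def relative_ankle_signal(
    traj: TrajectorySet,
    side: str,
    landmark: str | None = None,
    direction: float | None = None,
) -> np.ndarray:
    """Foot progression coordinate relative to the hip centre.

    Lateral and 3D-capture views use the horizontal progression axis of
    the ankle (or another foot landmark); near-frontal views use the
    vertical image coordinate of the heel.  The sign is oriented so that
    forward excursion of the foot is positive: by the toe−heel facing
    direction for lateral views, and by whether the subject approaches or
    recedes from a near-frontal camera.  ``direction`` overrides the
    automatic orientation (+1/−1).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if traj.view == "near_frontal":
        landmark = landmark or f"{side}_heel"
        if not traj.has(landmark):
            landmark = f"{side}_ankle"
        if not traj.has(landmark):
            raise ValueError(f"near-frontal signal needs {side} heel or ankle")
        axis = 1  # vertical image axis stands in for progression
        sign = direction if direction is not None else _approach_sign(traj)
        rel = traj.positions[landmark][:, axis] - hip_center(traj)[:, axis]
        return sign * rel
    landmark = landmark or f"{side}_ankle"
    if not traj.has(landmark):
        raise ValueError(f"landmark {landmark!r} missing for {side} signal")
    sign = direction if direction is not None else _facing_sign(traj)
    rel = traj.positions[landmark][:, 0] - hip_center(traj)[:, 0]
    return sign * rel


def _refine_parabolic(signal: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-frame vertex of the parabola through each peak and neighbours."""
    t = idx.astype(float)
    for j, i in enumerate(idx):
        if 0 < i < signal.size - 1:
            y0, y1, y2 = signal[i - 1], signal[i], signal[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                t[j] = i + 0.5 * (y0 - y2) / denom
    return t


def _alternate(
    hs_idx: np.ndarray, to_idx: np.ndarray, signal: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Enforce …HS, TO, HS… alternation, dropping the weaker duplicate."""
    events = [(int(i), "hs", float(signal[i])) for i in hs_idx]
    events += [(int(i), "to", float(-signal[i])) for i in to_idx]
    events.sort()
    cleaned: list[tuple[int, str, float]] = []
    for ev in events:
        if cleaned and cleaned[-1][1] == ev[1]:
            if ev[2] > cleaned[-1][2]:  # keep larger-magnitude extremum
                cleaned[-1] = ev
        else:
            cleaned.append(ev)
    hs = np.array([i for i, kind, _ in cleaned if kind == "hs"], dtype=int)
    to = np.array([i for i, kind, _ in cleaned if kind == "to"], dtype=int)
    return hs, to


def detect_events(
    signal: np.ndarray,
    frame_rate: float,
    side: str,
    min_stride_s: float = DEFAULT_MIN_STRIDE_S,
    source_view: str = "lateral",
    refine_subframe: bool = False,
    time_offset_s: float = 0.0,
    which: str = "both",
) -> GaitEvents:
    """Detect heel strikes (maxima) and toe-offs (minima) in a relative signal.

    The signal must be gap-free and filtered.  Peaks closer together than
    ``min_stride_s`` are merged keeping the larger one, a prominence floor
    of 25% of the signal's interquartile range rejects incidental ripples,
    and strict HS/TO alternation is enforced by dropping the weaker of two
    same-type neighbours.  ``which`` restricts detection to one event type
    (``"hs"`` or ``"to"``) for signals that only carry that event reliably;
    alternation is then skipped.  Fewer than two detected strides yields
    empty event lists with a warning.
    """
    signal = np.asarray(signal, dtype=float)
    if not min_stride_s > 0:
        raise ValueError("min_stride_s must be positive")
    if np.any(~np.isfinite(signal)):
        raise ValueError("event signal contains gaps; preprocess first")
    q75, q25 = np.percentile(signal, [75, 25])
    prominence = PROMINENCE_IQR_FRACTION * (q75 - q25)
    empty = GaitEvents(side, np.array([]), np.array([]), source_view)
    if prominence <= 0:
        _warnings.warn(f"{side}: flat signal, no gait events")
        return empty
    distance = max(1, int(round(min_stride_s * frame_rate)))
    hs_idx = to_idx = np.array([], dtype=int)
    if which in ("both", "hs"):
        hs_idx, _ = find_peaks(signal, distance=distance, prominence=prominence)
    if which in ("both", "to"):
        to_idx, _ = find_peaks(-signal, distance=distance, prominence=prominence)
    if which == "both":
        hs_idx, to_idx = _alternate(hs_idx, to_idx, signal)
    if hs_idx.size < 2 and which != "to":
        _warnings.warn(f"{side}: fewer than 2 strides detected")
        return empty
    hs_t = _refine_parabolic(signal, hs_idx) if refine_subframe else hs_idx.astype(float)
    to_t = _refine_parabolic(-signal, to_idx) if refine_subframe else to_idx.astype(float)
    return GaitEvents(
        side=side,
        heel_strikes=hs_t / frame_rate + time_offset_s,
        toe_offs=to_t / frame_rate + time_offset_s,
        source_view=source_view,
    )


def detect_gait_events(
    traj: TrajectorySet,
    side: str,
    min_stride_s: float = DEFAULT_MIN_STRIDE_S,
    direction: float | None = None,
    refine_subframe: bool = False,
) -> GaitEvents:
    """Detect events for one side directly from a trajectory.

    Lateral and 3D views use the ankle-relative progression signal for
    both event types.  Near-frontal views use the heel's vertical image
    excursion for heel strikes and the toe's for toe-offs (both relative
    to the hip centre), since those are the landmarks whose extremes
    coincide with ground contact and lift-off when progression runs along
    the optical axis.
    """
    if traj.view == "near_frontal":
        heel_sig = relative_ankle_signal(traj, side, direction=direction)
        ev_hs = _detect_bridged(
            heel_sig, traj.frame_rate, side, min_stride_s, traj.view,
            refine_subframe, which="hs",
        )
        toe = f"{side}_foot_index"
        toe_sig = (
            relative_ankle_signal(traj, side, landmark=toe, direction=direction)
            if traj.has(toe)
            else heel_sig
        )
        ev_to = _detect_bridged(
            toe_sig, traj.frame_rate, side, min_stride_s, traj.view,
            refine_subframe, which="to",
        )
        return GaitEvents(side, ev_hs.heel_strikes, ev_to.toe_offs, traj.view)
    sig = relative_ankle_signal(traj, side, direction=direction)
    return _detect_bridged(
        sig, traj.frame_rate, side, min_stride_s, traj.view, refine_subframe
    )


def _detect_bridged(
    signal: np.ndarray,
    frame_rate: float,
    side: str,
    min_stride_s: float,
    source_view: str,
    refine_subframe: bool,
    which: str = "both",
) -> GaitEvents:
    """Run detection across occlusion holes, then discard events inside them.

    Long occlusions are not interpolated by preprocessing, so the signal
    may still contain gaps; they are linearly bridged for peak finding
    only, and any event whose peak falls on bridged samples (or on an
    untrimmable edge gap) is dropped as fabricated.
    """
    signal = np.asarray(signal, dtype=float)
    valid = np.isfinite(signal)
    if valid.sum() < 4:
        _warnings.warn(f"{side}: too few valid samples for event detection")
        return GaitEvents(side, np.array([]), np.array([]), source_view)
    if valid.all():
        return detect_events(
            signal, frame_rate, side, min_stride_s,
            source_view=source_view, refine_subframe=refine_subframe,
            which=which,
        )
    idx = np.flatnonzero(valid)
    bridged = np.interp(np.arange(signal.size), idx, signal[idx])
    ev = detect_events(
        bridged, frame_rate, side, min_stride_s,
        source_view=source_view, refine_subframe=refine_subframe,
        which=which,
    )

    def keep(times: np.ndarray) -> np.ndarray:
        # an event is trusted only if the peak sample and its immediate
        # neighbourhood are real observations, not bridge interpolation
        k = np.clip(np.round(times * frame_rate).astype(int), 0, signal.size - 1)
        ok = np.ones(k.size, dtype=bool)
        for off in (-2, -1, 0, 1, 2):
            ok &= valid[np.clip(k + off, 0, signal.size - 1)]
        return times[ok]

    return GaitEvents(side, keep(ev.heel_strikes), keep(ev.toe_offs), source_view)


def pair_bilateral(left: GaitEvents, right: GaitEvents) -> list[Cycle]:
    """Validate bilateral events into the list of usable gait cycles.

    The merged chronological heel-strike sequence must alternate sides;
    any ipsilateral HS→HS interval that does not contain exactly one
    contralateral heel strike is discarded.  Within each surviving cycle
    the interior toe-offs are attached where present: the contralateral
    toe-off between the cycle's HS and the contralateral HS (terminal
    double support of the other limb), and the ipsilateral toe-off after
    the contralateral HS (this limb's stance end).
    """
    if left.heel_strikes.size == 0 or right.heel_strikes.size == 0:
        raise ValueError("both sides must have detected heel strikes")
    by_side = {"left": left, "right": right}
    cycles: list[Cycle] = []
    for side, ev in by_side.items():
        contra = by_side["right" if side == "left" else "left"]
        for k in range(ev.heel_strikes.size - 1):
            t0, t1 = ev.heel_strikes[k], ev.heel_strikes[k + 1]
            inside = contra.heel_strikes[
                (contra.heel_strikes > t0) & (contra.heel_strikes < t1)
            ]
            if inside.size != 1:
                continue  # alternation violated: discard this cycle
            hs_c = float(inside[0])
            to_c = contra.toe_offs[(contra.toe_offs > t0) & (contra.toe_offs < hs_c)]
            to_i = ev.toe_offs[(ev.toe_offs > hs_c) & (ev.toe_offs < t1)]
            if to_i.size == 0:
                # stance may end before the contralateral strike in fast gait
                to_i = ev.toe_offs[(ev.toe_offs > t0) & (ev.toe_offs < t1)]
            cycles.append(
                Cycle(
                    side=side,
                    index=k,
                    hs=float(t0),
                    hs_next=float(t1),
                    hs_contra=hs_c,
                    to_ipsi=float(to_i[0]) if to_i.size else None,
                    to_contra=float(to_c[0]) if to_c.size else None,
                )
            )
    if not cycles:
        raise ValueError("no valid gait cycle after bilateral validation")
    cycles.sort(key=lambda c: c.hs)
    return cycles
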
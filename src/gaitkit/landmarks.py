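"""Landmark vocabulary for pose-estimator output.

Markerless pose estimators of the MediaPipe family emit 33 named body
landmarks per frame.  Gait analysis consumes only the twelve lower-body /
trunk points listed in :data:`CONSUMED`; every other name in the 33-point
namespace is accepted and carried through untouched, and genuinely unknown
names are preserved but flagged so file-format problems surface early.

Coordinate convention (fixed for the whole package): image coordinates are
in pixels with the origin at the top-left corner and y increasing
*downward* — the native convention of pose-estimator output.  3D motion
capture trajectories use metres-scale units (millimetres by default) with
x along the direction of progression and y vertical, increasing upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    CENTER = "center"


class BodyPoint(str, Enum):
    SHOULDER = "shoulder"
    HIP = "hip"
    KNEE = "knee"
    ANKLE = "ankle"
    HEEL = "heel"
    TOE = "toe"
    OTHER = "other"


@dataclass(frozen=True)
class Landmark:
    """A named landmark resolved to a (body point, side) pair."""

    name: str
    point: BodyPoint
    side: Side
    known: bool = True


#: The full 33-landmark namespace of MediaPipe-style pose output, in index order.
MEDIAPIPE_33 = (
    "nose",
    "left_eye_inner", "left_eye", "left_eye_outer",
    "right_eye_inner", "right_eye", "right_eye_outer",
    "left_ear", "right_ear",
    "mouth_left", "mouth_right",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_pinky", "right_pinky",
    "left_index", "right_index",
    "left_thumb", "right_thumb",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_heel", "right_heel",
    "left_foot_index", "right_foot_index",
)

# name -> (BodyPoint, Side) for the points gait analysis consumes.
_CONSUMED_MAP = {
    "left_shoulder": (BodyPoint.SHOULDER, Side.LEFT),
    "right_shoulder": (BodyPoint.SHOULDER, Side.RIGHT),
    "left_hip": (BodyPoint.HIP, Side.LEFT),
    "right_hip": (BodyPoint.HIP, Side.RIGHT),
    "left_knee": (BodyPoint.KNEE, Side.LEFT),
    "right_knee": (BodyPoint.KNEE, Side.RIGHT),
    "left_ankle": (BodyPoint.ANKLE, Side.LEFT),
    "right_ankle": (BodyPoint.ANKLE, Side.RIGHT),
    "left_heel": (BodyPoint.HEEL, Side.LEFT),
    "right_heel": (BodyPoint.HEEL, Side.RIGHT),
    "left_foot_index": (BodyPoint.TOE, Side.LEFT),
    "right_foot_index": (BodyPoint.TOE, Side.RIGHT),
}

# Accepted aliases for the toe point ("foot index" is the pose-estimator name).
_ALIASES = {
    "left_toe": "left_foot_index",
    "right_toe": "right_foot_index",
    "left_foot": "left_foot_index",
    "right_foot": "right_foot_index",
}

#: Canonical names of the twelve consumed landmarks.
CONSUMED = tuple(_CONSUMED_MAP)


def canonical_name(name: str) -> str:
    """Map accepted aliases onto canonical landmark names."""
    return _ALIASES.get(name.strip().lower(), name.strip().lower())


def resolve(name: str) -> Landmark:
    """Resolve a landmark name to its (body point, side) classification.

    Names in the 33-landmark namespace that gait analysis does not consume
    resolve to ``BodyPoint.OTHER`` with a best-effort side; names outside
    the namespace are preserved but marked ``known=False``.
    """
    cname = canonical_name(name)
    if cname in _CONSUMED_MAP:
        point, side = _CONSUMED_MAP[cname]
        return Landmark(cname, point, side)
    if cname in MEDIAPIPE_33:
        if cname.startswith("left_") or cname == "mouth_left":
            side = Side.LEFT
        elif cname.startswith("right_") or cname == "mouth_right":
            side = Side.RIGHT
        else:
            side = Side.CENTER
        return Landmark(cname, BodyPoint.OTHER, side)
    return Landmark(cname, BodyPoint.OTHER, Side.CENTER, known=False)


def landmark_name(point: BodyPoint | str, side: Side | str) -> str:
    """Canonical name of a consumed (body point, side) pair."""
    point = BodyPoint(point)
    side = Side(side)
    for name, (p, s) in _CONSUMED_MAP.items():
        if p == point and s == side:
            return name
    raise KeyError(f"no consumed landmark for ({point.value}, {side.value})")


def other_side(side: Side | str) -> Side:
    side = Side(side)
    if side == Side.LEFT:
        return Side.RIGHT
    if side == Side.RIGHT:
        return Side.LEFT
    raise ValueError("center has no contralateral side")
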
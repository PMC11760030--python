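"""Core trajectory containers.

A :class:`TrajectorySet` holds time-indexed landmark positions plus
per-sample visibility for one recording of one subject.  Positions are
stored as float arrays of shape ``(n_frames, ndim)`` per landmark; a
missing sample (a *gap*) is represented as NaN coordinates with zero
visibility — never as a sentinel value, and never as NaN with visibility 1.
Frame ``k`` occurs at ``k / frame_rate`` seconds from the trajectory's own
epoch; alignment across recording systems is the synchronisation step's
job, not the container's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

VIEWS = ("lateral", "near_frontal", "mocap3d")
CONDITIONS = ("treadmill", "overground_forward", "overground_backward")


@dataclass
class TrajectorySet:
    """Time-indexed landmark positions and visibility at one frame rate.

    Parameters
    ----------
    frames : (n,) int array
        Strictly increasing frame numbers.
    positions : dict of str -> (n, ndim) float array
        Per-landmark coordinates: pixels for 2D video (x right, y down),
        millimetres for 3D capture (x progression, y up, z mediolateral).
    visibility : dict of str -> (n,) float array
        Per-sample confidence in [0, 1]; 1 where a capture system reports
        no confidence of its own; exactly 0 wherever a position is a gap.
    frame_rate : float
        Sampling rate in Hz.
    view : str
        One of ``lateral``, ``near_frontal``, ``mocap3d``.
    """

    frames: np.ndarray
    positions: dict[str, np.ndarray]
    visibility: dict[str, np.ndarray]
    frame_rate: float
    view: str
    subject_id: str = "s0"
    condition: str = "treadmill"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        if self.frames.ndim != 1:
            raise ValueError("frames must be a 1-D index")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame index must be strictly increasing")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        n = self.frames.size
        for name, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape[0] != n:
                raise ValueError(f"{name}: {pos.shape[0]} samples for {n} frames")
            self.positions[name] = pos
            vis = np.asarray(
                self.visibility.get(name, np.ones(n)), dtype=float
            )
            if vis.shape != (n,):
                raise ValueError(f"{name}: visibility shape {vis.shape}")
            if np.any((vis < 0) | (vis > 1)):
                raise ValueError(f"{name}: visibility outside [0, 1]")
            gap = np.any(np.isnan(pos), axis=1)
            if np.any(gap & (vis >= 1.0)):
                raise ValueError(
                    f"{name}: NaN position with visibility 1 (gaps must have "
                    "visibility < 1; use set_gap)"
                )
            # a gap is a gap in every coordinate, with zero visibility
            pos[gap] = np.nan
            vis = vis.copy()
            vis[gap] = 0.0
            self.visibility[name] = vis

    # -- basic geometry -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)

    @property
    def ndim(self) -> int:
        for pos in self.positions.values():
            return int(pos.shape[1])
        return 0

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from the trajectory's own epoch."""
        return (self.frames - self.frames[0]) / self.frame_rate

    def landmarks(self) -> list[str]:
        return list(self.positions)

    def has(self, name: str) -> bool:
        return name in self.positions

    def get(self, name: str) -> np.ndarray:
        if name not in self.positions:
            raise KeyError(f"landmark {name!r} not present in trajectory")
        return self.positions[name]

    def valid_mask(self, name: str) -> np.ndarray:
        """True where the landmark has a (non-gap) sample."""
        return ~np.any(np.isnan(self.get(name)), axis=1)

    def set_gap(self, name: str, index: np.ndarray) -> None:
        """Turn the given sample indices of a landmark into gaps in place."""
        self.positions[name][index] = np.nan
        self.visibility[name][index] = 0.0

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(
            frames=self.frames.copy(),
            positions={k: v.copy() for k, v in self.positions.items()},
            visibility={k: v.copy() for k, v in self.visibility.items()},
            frame_rate=self.frame_rate,
            view=self.view,
            subject_id=self.subject_id,
            condition=self.condition,
            meta=dict(self.meta),
        )

    def equals(self, other: "TrajectorySet", atol: float = 0.0) -> bool:
        if (
            self.view != other.view
            or not math.isclose(self.frame_rate, other.frame_rate)
            or self.n_frames != other.n_frames
            or set(self.positions) != set(other.positions)
            or not np.array_equal(self.frames, other.frames)
        ):
            return False
        for name in self.positions:
            a, b = self.positions[name], other.positions[name]
            if a.shape != b.shape:
                return False
            if not np.allclose(a, b, atol=atol, equal_nan=True):
                return False
            if not np.allclose(self.visibility[name], other.visibility[name], atol=atol):
                return False
        return True


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-metre scale from two image points a known distance apart.

    The field protocol marks two points on the floor (for a 6 m walkway,
    the two lines bounding it) and measures their real separation; the
    image-plane distance between them fixes the pixels-per-metre scale of
    a lateral, approximately fronto-parallel camera.
    """

    point_a_px: tuple[float, float]
    point_b_px: tuple[float, float]
    known_distance_m: float
    pixels_per_meter: float

    def __post_init__(self) -> None:
        if not self.pixels_per_meter > 0:
            raise ValueError("pixels_per_meter must be positive")
        ax, ay = self.point_a_px
        bx, by = self.point_b_px
        recomputed = math.hypot(bx - ax, by - ay) / self.known_distance_m
        if not math.isclose(recomputed, self.pixels_per_meter, rel_tol=1e-9):
            raise ValueError("pixels_per_meter inconsistent with its inputs")

    def px_to_m(self, value_px: float | np.ndarray) -> float | np.ndarray:
        return value_px / self.pixels_per_meter
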
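"""Trajectory denoising and conditioning.

The processing order is fixed: spike samples are turned into gaps wherever
the per-landmark acceleration (central second difference, pixels/frame²)
crosses a threshold, gaps up to a maximum length are refilled by cubic
interpolation, and only then is a zero-lag low-pass Butterworth filter
applied.  Zero lag is realised as forward–backward filtering, which squares
the design's magnitude response and cancels its phase; the effective
attenuation of an order-``n`` design at frequency ``f`` is therefore
``1 / (1 + (f / cutoff)**(2 n))``.

Gaps longer than ``max_gap_frames`` are deliberately left unfilled: cubic
interpolation across a long occlusion fabricates motion, and downstream
stages are expected to discard events that span such holes.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .trajectory import TrajectorySet

#: shortest run of consistent walking direction that counts as a pass (s)
MIN_PASS_S = 1.0
#: guard band trimmed from each end of a pass, where the turning motion
#: and the camera-angle transition corrupt steps (s)
PASS_GUARD_S = 0.5


@dataclass
class PreprocessConfig:
    """Tunable preprocessing settings.

    ``accel_threshold`` is in pixels/frame² (or mm/frame² for capture
    data); ``None`` selects a robust per-landmark default of 5× the median
    absolute second difference of that landmark's own series, which adapts
    to pixel scale.  ``cutoff_hz`` must stay below the Nyquist rate.
    """

    accel_threshold: float | None = None
    cutoff_hz: float = 5.0
    filter_order: int = 4
    max_gap_frames: int = 10

    def validate(self, frame_rate: float) -> None:
        if self.accel_threshold is not None and not self.accel_threshold > 0:
            raise ValueError("accel_threshold must be positive")
        if not self.cutoff_hz < frame_rate / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must be below Nyquist "
                f"({frame_rate / 2} Hz)"
            )
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.max_gap_frames < 1:
            raise ValueError("max_gap_frames must be >= 1")


def _second_difference_mag(pos: np.ndarray) -> np.ndarray:
    """Central second-difference magnitude; NaN where undefined."""
    d2 = np.full(pos.shape[0], np.nan)
    if pos.shape[0] >= 3:
        core = pos[2:] - 2.0 * pos[1:-1] + pos[:-2]
        d2[1:-1] = np.linalg.norm(core, axis=1)
    return d2


def _gap_runs(invalid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of invalid samples as half-open (start, stop) pairs."""
    runs = []
    n = invalid.size
    i = 0
    while i < n:
        if invalid[i]:
            j = i
            while j < n and invalid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def despike_and_fill(
    traj: TrajectorySet, cfg: PreprocessConfig | None = None
) -> TrajectorySet:
    """Gap out acceleration spikes and refill short gaps by cubic interpolation.

    Spikes are samples whose second-difference magnitude exceeds the
    threshold.  Gaps no longer than ``cfg.max_gap_frames`` are refilled
    with a not-a-knot cubic spline over the landmark's valid samples
    (exact for any cubic trajectory); gaps at the series ends are never
    extrapolated, and longer gaps remain gaps.  A landmark with fewer
    than 4 valid samples passes through unchanged with a warning record
    in ``meta['preprocess_warnings']``.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(traj.frame_rate)
    out = traj.copy()
    warnings: list[str] = out.meta.setdefault("preprocess_warnings", [])
    for name in out.landmarks():
        pos = out.positions[name]
        valid = out.valid_mask(name)
        if valid.sum() < 4:
            warnings.append(f"{name}: fewer than 4 valid samples, left unchanged")
            continue
        d2 = _second_difference_mag(pos)
        if cfg.accel_threshold is not None:
            threshold = cfg.accel_threshold
        else:
            finite = d2[np.isfinite(d2)]
            # floor keeps a near-noiseless series from flagging everything
            threshold = 5.0 * max(
                float(np.median(finite)) if finite.size else 0.0, 1e-9
            )
        spikes = np.isfinite(d2) & (d2 > threshold)
        if spikes.any():
            out.set_gap(name, np.flatnonzero(spikes))
            valid = out.valid_mask(name)
        if valid.sum() < 4:
            warnings.append(f"{name}: fewer than 4 samples after despiking")
            continue
        idx = np.flatnonzero(valid)
        spline = CubicSpline(idx, out.positions[name][idx], axis=0)
        for start, stop in _gap_runs(~valid):
            if start == 0 or stop == valid.size:
                continue  # endpoint gaps: never extrapolate
            if stop - start > cfg.max_gap_frames:
                warnings.append(
                    f"{name}: gap of {stop - start} frames at {start} left unfilled"
                )
                continue
            fill = np.arange(start, stop)
            out.positions[name][fill] = spline(fill)
            # interpolated samples are marked by a sub-unity visibility
            out.visibility[name][fill] = np.nextafter(1.0, 0.0)
    return out


def lowpass_zero_lag(
    traj: TrajectorySet,
    cfg: PreprocessConfig | None = None,
    allow_gaps: bool = False,
) -> TrajectorySet:
    """Zero-lag Butterworth low-pass, per landmark and coordinate.

    By default any remaining gap is an error (run :func:`despike_and_fill`
    first).  With ``allow_gaps=True`` each contiguous valid segment is
    filtered independently and segments no longer than the filter's
    warm-up length (``3 * (order + 1)`` samples) are passed through
    unchanged.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(traj.frame_rate)
    b, a = butter(cfg.filter_order, cfg.cutoff_hz, fs=traj.frame_rate)
    padlen = 3 * max(len(a), len(b))
    out = traj.copy()
    for name in out.landmarks():
        pos = out.positions[name]
        valid = out.valid_mask(name)
        if not valid.all() and not allow_gaps:
            raise ValueError(
                f"{name} still has gaps; fill gaps (despike_and_fill) before "
                "low-pass filtering or pass allow_gaps=True"
            )
        for start, stop in _gap_runs(valid):  # runs of *valid* samples
            if stop - start <= padlen:
                continue
            pos[start:stop] = filtfilt(b, a, pos[start:stop], axis=0)
    return out


def downsample(traj: TrajectorySet, target_fps: float) -> TrajectorySet:
    """Reduce a trajectory's frame rate to ``target_fps``.

    When the source rate is an integer multiple of the target, decimation
    keeps every ``rate/target``-th frame starting at frame 0; otherwise
    the series is linearly resampled onto the target grid.
    """
    if target_fps > traj.frame_rate:
        raise ValueError(
            f"target {target_fps} fps exceeds source rate {traj.frame_rate} fps"
        )
    ratio = traj.frame_rate / target_fps
    out = traj.copy()
    if abs(ratio - round(ratio)) < 1e-9:
        step = int(round(ratio))
        if step == 1:
            return out
        keep = np.arange(0, traj.n_frames, step)
        out.frames = np.arange(keep.size)
        out.positions = {k: v[keep].copy() for k, v in out.positions.items()}
        out.visibility = {k: v[keep].copy() for k, v in out.visibility.items()}
        out.frame_rate = target_fps
        return out
    t_src = traj.times()
    n_out = int(np.floor(t_src[-1] * target_fps)) + 1
    t_out = np.arange(n_out) / target_fps
    positions = {}
    visibility = {}
    for name, pos in traj.positions.items():
        res = np.column_stack(
            [np.interp(t_out, t_src, pos[:, j]) for j in range(pos.shape[1])]
        )
        vis = np.interp(t_out, t_src, traj.visibility[name])
        gap = np.any(np.isnan(res), axis=1)
        vis[gap] = 0.0
        positions[name] = res
        visibility[name] = vis
    out.frames = np.arange(n_out)
    out.positions = positions
    out.visibility = visibility
    out.frame_rate = target_fps
    return out


def trim_sync(traj: TrajectorySet, start_s: float, end_s: float) -> TrajectorySet:
    """Keep the window [start_s, end_s) and re-zero the frame index.

    Synchronisation offsets between recording systems (for instance from a
    colour-change sync event detected upstream) are applied here; the
    retained duration matches ``end_s - start_s`` to within one frame.
    """
    duration = traj.n_frames / traj.frame_rate
    if not (0.0 <= start_s < end_s):
        raise ValueError(f"empty or inverted trim window ({start_s}, {end_s})")
    if start_s >= duration:
        raise ValueError(f"trim window starts after the trajectory ends")
    end_s = min(end_s, duration)
    t = traj.times()
    keep = np.flatnonzero((t >= start_s - 1e-9) & (t < end_s - 1e-9))
    if keep.size == 0:
        raise ValueError("trim window contains no frames")
    out = traj.copy()
    out.frames = np.arange(keep.size)
    out.positions = {k: v[keep].copy() for k, v in out.positions.items()}
    out.visibility = {k: v[keep].copy() for k, v in out.visibility.items()}
    out.meta = dict(out.meta, trim_window_s=(float(start_s), float(end_s)))
    return out


def _slice_frames(traj: TrajectorySet, start: int, stop: int) -> TrajectorySet:
    out = traj.copy()
    out.frames = np.arange(stop - start)
    out.positions = {k: v[start:stop].copy() for k, v in traj.positions.items()}
    out.visibility = {k: v[start:stop].copy() for k, v in traj.visibility.items()}
    out.meta = dict(traj.meta, source_frames=(int(start), int(stop)))
    return out


def segment_passes(
    traj: TrajectorySet,
    min_pass_s: float = MIN_PASS_S,
    guard_s: float = PASS_GUARD_S,
) -> list[tuple[TrajectorySet, str]]:
    """Split an overground trajectory into straight walking passes.

    The hip-centre progression velocity is smoothed over 0.25 s; maximal
    runs of consistent velocity sign lasting at least ``min_pass_s``
    become passes labelled ``rightward`` (increasing coordinate) or
    ``leftward``.  Turn intervals between passes are discarded, and a
    guard band of ``guard_s`` is trimmed from each end of every pass
    because steps adjacent to a turn are unreliable.
    """
    hips = [n for n in ("left_hip", "right_hip") if traj.has(n)]
    if not hips:
        raise ValueError("hip landmarks required to segment passes")
    if traj.view == "near_frontal":
        # progression runs along the optical axis: apparent trunk size is
        # the progression proxy (it grows as the subject approaches)
        pairs = [
            np.abs(traj.positions[s][:, 1] - traj.positions[h][:, 1])
            for s, h in (("left_shoulder", "left_hip"), ("right_shoulder", "right_hip"))
            if traj.has(s) and traj.has(h)
        ]
        if not pairs:
            raise ValueError("near-frontal pass segmentation needs shoulders")
        x = np.nanmean(pairs, axis=0)
    else:
        x = np.nanmean([traj.positions[n][:, 0] for n in hips], axis=0)
    x = np.where(np.isnan(x), np.interp(
        np.arange(x.size), np.flatnonzero(~np.isnan(x)), x[~np.isnan(x)]
    ), x) if np.isnan(x).any() and (~np.isnan(x)).any() else x
    v = np.gradient(x) * traj.frame_rate
    win = max(1, int(round(0.25 * traj.frame_rate)))
    kernel = np.ones(win) / win
    v_smooth = np.convolve(v, kernel, mode="same")
    speed_scale = float(np.percentile(np.abs(v_smooth), 90))
    v_thresh = 0.25 * speed_scale
    sign = np.where(v_smooth > v_thresh, 1, np.where(v_smooth < -v_thresh, -1, 0))

    passes: list[tuple[TrajectorySet, str]] = []
    min_len = int(round(min_pass_s * traj.frame_rate))
    guard = int(round(guard_s * traj.frame_rate))
    i = 0
    n = sign.size
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j < n and sign[j] == sign[i]:
            j += 1
        if j - i >= min_len:
            start, stop = i + guard, j - guard
            if stop - start > 0:
                label = "rightward" if sign[i] > 0 else "leftward"
                passes.append((_slice_frames(traj, start, stop), label))
        i = j
    if not passes:
        _warnings.warn("no walking pass of sufficient duration found")
    return passes
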
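"""Synthetic gait generator with exact ground truth.

The generator stands in for recorded walking data: it produces keypoint
trajectories for a lateral camera (orthographic), a near-frontal camera
(perspective, progression along the optical axis), and a 3D capture
system (millimetres, 240 Hz), all views of the *same* underlying planar
lower-limb motion, together with the exact event times, per-cycle
parameters, and noiseless angle traces that measurement code should
recover.

The motion is kinematically prescribed, not dynamically simulated — the
package tests measurement code, not biomechanics, and ground truth must
be exact.  The construction works backwards from what event detection
measures: the ankle's progression-axis position relative to the hip
centre is prescribed directly as a cosine in a warped gait phase, so its
forward extreme falls *exactly* at heel strike (phase 0) and its backward
extreme exactly at toe-off (phase = stance fraction).  Ankle height and
foot pitch follow piecewise-smooth profiles (flat foot, late-stance heel
rise pivoting about the toe, swing clearance), and the hip and knee
angles are then derived by two-link inverse kinematics from the hip to
the prescribed ankle.  Joint-angle ranges of motion are consequences of
the geometry; the defaults are tuned so they land near typical overground
values (hip ≈ 29°, knee ≈ 55°, ankle ≈ 24°).

Pose-estimation imperfections are modelled last: Gaussian landmark
jitter, occasional spike outliers, and occlusion-driven visibility loss
(an AR(1) visibility score per landmark around a per-landmark mean;
samples under a floor become gaps, and jitter inflates as visibility
drops).  The default visibility means reproduce the strong near/far-side
asymmetry of a single side camera — e.g. a far-side knee around 0.27
against a near-side knee around 0.92 on a treadmill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import kinematics, parameters
from .gait_events import GaitEvents, pair_bilateral
from .trajectory import TrajectorySet

_GROUND_CLEAR = 0.01  # sole thickness: heel/toe resting height (m)


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass
class GaitSpec:
    """Kinematic prescription of one subject's gait.

    Units: seconds, metres, degrees.  ``stance_fraction`` is the fraction
    of the stride spent in stance (toe-off phase).  Segment lengths and
    pelvis geometry control the inverse-kinematics solution and hence the
    emergent joint-angle ranges.
    """

    stride_time: float = 1.1
    stance_fraction: float = 0.62
    step_length: float = 0.55
    thigh_m: float = 0.44
    shank_m: float = 0.44
    hip_height_m: float = 0.935
    pelvis_rise_m: float = 0.02
    ankle_height_m: float = 0.09
    rel_offset_m: float = -0.07
    toe_offset_m: tuple[float, float] = (0.16, -0.08)
    heel_offset_m: tuple[float, float] = (-0.07, -0.08)
    heel_rise_deg: float = 40.0
    swing_ankle_lift_deg: float = 12.0
    heel_rise_onset: float = 0.55
    swing_peak_rise_m: float = 0.13
    swing_peak_pos: float = 0.45
    trunk_len_m: float = 0.53
    trunk_lean_m: float = 0.03
    pelvis_width_m: float = 0.22
    shoulder_width_m: float = 0.34
    foot_ml_m: float = 0.11
    ml_sway_m: float = 0.025
    walk_mode: str = "treadmill"  # or "overground"
    bout_duration_s: float = 30.0
    walkway_m: float = 6.0
    n_round_trips: int = 2
    turn_duration_s: float = 1.5
    fps: float = 30.0

    def validate(self) -> None:
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.stride_time <= 0 or self.step_length <= 0 or self.fps <= 0:
            raise ValueError("stride_time, step_length and fps must be positive")
        if self.thigh_m <= 0 or self.shank_m <= 0:
            raise ValueError("segment lengths must be positive")
        if self.walk_mode not in ("treadmill", "overground"):
            raise ValueError("walk_mode must be 'treadmill' or 'overground'")


# Mean landmark visibility per (condition, view, landmark) for a single
# side camera, reproducing the occlusion asymmetry of real recordings:
# the limb away from the camera is frequently hidden by the body.
VISIBILITY_PROFILES: dict[tuple[str, str], dict[str, float]] = {
    ("treadmill", "lateral"): {
        "left_shoulder": 1.0, "right_shoulder": 0.9998,
        "left_hip": 1.0, "right_hip": 1.0,
        "left_knee": 0.9183, "right_knee": 0.2738,
        "left_ankle": 0.9393, "right_ankle": 0.5758,
        "left_heel": 0.8223, "right_heel": 0.6310,
        "left_foot_index": 0.9413, "right_foot_index": 0.7237,
    },
    ("treadmill", "near_frontal"): {
        "left_shoulder": 1.0, "right_shoulder": 1.0,
        "left_hip": 1.0, "right_hip": 1.0,
        "left_knee": 0.9470, "right_knee": 0.9650,
        "left_ankle": 0.9472, "right_ankle": 0.9652,
        "left_heel": 0.7816, "right_heel": 0.7316,
        "left_foot_index": 0.9594, "right_foot_index": 0.9582,
    },
    ("overground_forward", "lateral"): {
        "left_shoulder": 0.9995, "right_shoulder": 0.9999,
        "left_hip": 0.9983, "right_hip": 0.9994,
        "left_knee": 0.8689, "right_knee": 0.9842,
        "left_ankle": 0.8912, "right_ankle": 0.9797,
        "left_heel": 0.9033, "right_heel": 0.9823,
        "left_foot_index": 0.7563, "right_foot_index": 0.9267,
    },
    ("overground_forward", "near_frontal"): {
        "left_shoulder": 0.9999, "right_shoulder": 0.9995,
        "left_hip": 0.9997, "right_hip": 0.9993,
        "left_knee": 0.9878, "right_knee": 0.8507,
        "left_ankle": 0.9859, "right_ankle": 0.9053,
        "left_heel": 0.9821, "right_heel": 0.9113,
        "left_foot_index": 0.9430, "right_foot_index": 0.8094,
    },
    ("overground_backward", "lateral"): {
        "left_shoulder": 0.9999, "right_shoulder": 0.9995,
        "left_hip": 0.9994, "right_hip": 0.9983,
        "left_knee": 0.9844, "right_knee": 0.8693,
        "left_ankle": 0.9800, "right_ankle": 0.8931,
        "left_heel": 0.9826, "right_heel": 0.9048,
        "left_foot_index": 0.9278, "right_foot_index": 0.7616,
    },
    ("overground_backward", "near_frontal"): {
        "left_shoulder": 0.9998, "right_shoulder": 1.0,
        "left_hip": 0.9994, "right_hip": 0.9996,
        "left_knee": 0.9180, "right_knee": 0.9693,
        "left_ankle": 0.9133, "right_ankle": 0.9575,
        "left_heel": 0.8620, "right_heel": 0.7999,
        "left_foot_index": 0.9296, "right_foot_index": 0.9513,
    },
}


@dataclass
class NoiseSpec:
    """Pose-estimation noise and occlusion model for video views.

    ``visibility_profile`` maps landmark names to mean visibility; when
    ``None`` the default profile for the trajectory's (condition, view)
    pair is used.  Samples whose AR(1)-fluctuating visibility falls under
    ``visibility_floor`` become gaps, and jitter grows by
    ``occlusion_noise_factor × (1 − visibility)`` as landmarks become
    harder to see.
    """

    jitter_sd_px: float = 2.0
    spike_rate: float = 0.005
    spike_magnitude_px: float = 40.0
    visibility_profile: dict[str, float] | None = None
    visibility_floor: float = 0.5
    visibility_ar_rho: float = 0.9
    visibility_ar_sd: float = 0.12
    occlusion_noise_factor: float = 2.0

    def validate(self) -> None:
        if self.jitter_sd_px < 0 or self.spike_magnitude_px < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValueError("spike_rate must lie in [0, 1]")
        if not 0.0 <= self.visibility_floor <= 1.0:
            raise ValueError("visibility_floor must lie in [0, 1]")

    @classmethod
    def noiseless(cls) -> "NoiseSpec":
        return cls(
            jitter_sd_px=0.0,
            spike_rate=0.0,
            visibility_profile={},
            visibility_ar_sd=0.0,
        )


@dataclass
class CameraSpec:
    """Projection parameters for the two video views."""

    pixels_per_meter: float = 320.0  # lateral scale: ~1920 px across a 6 m walkway
    image_center: tuple[float, float] = (960.0, 540.0)
    camera_side: str = "left"  # lateral camera placement
    focal_px: float = 1000.0  # near-frontal pinhole focal length
    camera_height_m: float = 1.3
    camera_distance_m: float = 3.5  # ahead of the walk's far end
    distortion_k: float = 0.0  # radial quadratic term; barrel < 0


@dataclass
class GaitGroundTruth:
    """Exact events, parameters, and noiseless angle traces."""

    events_left: GaitEvents
    events_right: GaitEvents
    cycles: list
    temporal: object  # per-cycle DataFrame (parameters.temporal_params)
    spatial: object  # per-step DataFrame
    angles_deg: dict[tuple[str, str], np.ndarray]
    pass_bounds: list[tuple[float, float, str]]
    pixels_per_meter: float | None
    spec: GaitSpec = None


# ---------------------------------------------------------------------------
# phase profiles
# ---------------------------------------------------------------------------


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _phase_warp(phi: np.ndarray, sf: float) -> np.ndarray:
    """Map stride phase [0,1) onto [0,2π): stance → [0,π], swing → [π,2π]."""
    phi = np.mod(phi, 1.0)
    return np.where(
        phi < sf,
        np.pi * phi / sf,
        np.pi + np.pi * (phi - sf) / (1.0 - sf),
    )


def _stance_pitch_deg(phi: np.ndarray, spec: GaitSpec) -> np.ndarray:
    """Stance foot pitch: 0 = flat; positive = heel raised (toe pivot).

    Only meaningful for phases inside stance; swing pitch is derived
    later from the shank direction (see :func:`_leg_sagittal`), because a
    swinging foot rides with the shank rather than holding a world-frame
    orientation.
    """
    sf = spec.stance_fraction
    phi = np.mod(phi, 1.0)
    beta = np.zeros_like(phi)
    onset = spec.heel_rise_onset * sf
    in_rise = phi >= onset
    beta[in_rise] = spec.heel_rise_deg * _smoothstep(
        (np.minimum(phi[in_rise], sf) - onset) / (sf - onset)
    )
    return beta


def _rot_minus_beta(offset: tuple[float, float], beta_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a foot-frame offset by −β (heel-rise direction, facing +x)."""
    b = np.radians(beta_deg)
    x, z = offset
    return x * np.cos(b) + z * np.sin(b), -x * np.sin(b) + z * np.cos(b)


def _ankle_height(phi: np.ndarray, spec: GaitSpec) -> np.ndarray:
    """Ankle height: toe-pivot during stance heel rise, clearance in swing."""
    sf = spec.stance_fraction
    phi = np.mod(phi, 1.0)
    beta = _stance_pitch_deg(phi, spec)
    tx, tz = spec.toe_offset_m
    # stance: the toe stays on the ground, so the ankle rides on it
    _, toe_dz = _rot_minus_beta((tx, tz), beta)
    z = _GROUND_CLEAR - toe_dz
    # swing: prescribed clearance profile between toe-off and the next strike
    swing = phi >= sf
    if np.any(swing):
        beta_to = np.array([spec.heel_rise_deg])
        _, toe_dz_to = _rot_minus_beta((tx, tz), beta_to)
        z_to = float(_GROUND_CLEAR - toe_dz_to[0])
        z_peak = spec.ankle_height_m + spec.swing_peak_rise_m
        u = (phi[swing] - sf) / (1.0 - sf)
        p = spec.swing_peak_pos
        seg1 = z_to + (z_peak - z_to) * _smoothstep(u / p)
        seg2 = z_peak + (spec.ankle_height_m - z_peak) * _smoothstep((u - p) / (1.0 - p))
        z[swing] = np.where(u < p, seg1, seg2)
    return z


def max_step_length(spec: GaitSpec) -> float:
    """Longest step the leg geometry can reach without hyperextension.

    The binding pose is the heel strike: the ankle is at its forward
    extreme with the pelvis at its event height, so the hip–ankle
    distance there must stay inside the two-link reach.
    """
    sf = spec.stance_fraction
    h_event = spec.hip_height_m - spec.pelvis_rise_m * math.cos(
        2.0 * math.pi * (sf - 0.5)
    )
    vert = h_event - spec.ankle_height_m
    reach = 0.999 * (spec.thigh_m + spec.shank_m)
    if vert >= reach:
        raise ValueError("hip_height_m exceeds leg reach even standing")
    x_max = math.sqrt(reach * reach - vert * vert)
    a1_max = x_max - spec.rel_offset_m  # rel_offset is negative: adds room
    psi_half = float(_phase_warp(np.array([0.5]), sf)[0])
    hx0, _ = _rot_minus_beta(spec.heel_offset_m, _stance_pitch_deg(np.array([0.0]), spec))
    hxh, _ = _rot_minus_beta(spec.heel_offset_m, _stance_pitch_deg(np.array([0.5]), spec))
    return a1_max * (1.0 - math.cos(psi_half)) + (float(hx0[0]) - float(hxh[0]))


def _rel_amplitude(spec: GaitSpec) -> float:
    """Solve the ankle-excursion amplitude that yields the requested step length.

    At a heel strike the striking heel sits at the forward extreme while
    the contralateral heel is half a stride out of phase; the heel
    separation is linear in the excursion amplitude, so the amplitude
    follows in closed form.
    """
    sf = spec.stance_fraction
    psi_half = float(_phase_warp(np.array([0.5]), sf)[0])
    hx0, _ = _rot_minus_beta(spec.heel_offset_m, _stance_pitch_deg(np.array([0.0]), spec))
    hxh, _ = _rot_minus_beta(spec.heel_offset_m, _stance_pitch_deg(np.array([0.5]), spec))
    denom = 1.0 - math.cos(psi_half)
    a1 = (spec.step_length - (float(hx0[0]) - float(hxh[0]))) / denom
    if a1 <= 0:
        raise ValueError("step_length too small for the foot geometry")
    return a1


def _ankle_x(phi: np.ndarray, spec: GaitSpec, a1: float) -> np.ndarray:
    return spec.rel_offset_m + a1 * np.cos(_phase_warp(phi, spec.stance_fraction))


def _knee_ik(
    ankle_x: np.ndarray,
    ankle_z: np.ndarray,
    pelvis_z: np.ndarray,
    spec: GaitSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-link inverse kinematics: knee position, bowing anteriorly."""
    vx = ankle_x
    vz = ankle_z - pelvis_z
    d = np.hypot(vx, vz)
    l1, l2 = spec.thigh_m, spec.shank_m
    reach = 0.999 * (l1 + l2)
    if np.any(d > reach):
        k = int(np.argmax(d > reach))
        raise ValueError(
            f"prescribed motion requires leg hyperextension at frame {k} "
            f"(hip–ankle distance {d[k]:.3f} m > reach {reach:.3f} m); "
            "lower hip_height_m or shorten step_length"
        )
    d = np.minimum(d, reach)
    cos_a = np.clip((l1 * l1 + d * d - l2 * l2) / (2.0 * l1 * d), -1.0, 1.0)
    alpha = np.arccos(cos_a)
    ux, uz = vx / d, vz / d
    # rotate the hip→ankle direction by +α (CCW): the knee bows anteriorly
    kx = np.cos(alpha) * ux - np.sin(alpha) * uz
    kz = np.sin(alpha) * ux + np.cos(alpha) * uz
    return l1 * kx, pelvis_z + l1 * kz


def _pelvis_height(phi: np.ndarray, spec: GaitSpec) -> np.ndarray:
    """Hip-centre height: twice-per-stride bob, lowest at mid double support.

    Troughs sit halfway through each double-support interval — i.e.
    ``(stance_fraction − 0.5) / 2`` of a stride after each heel strike —
    so the pelvis is falling through both heel strikes, as in walking.
    """
    trough = (spec.stance_fraction - 0.5) / 2.0
    return spec.hip_height_m - spec.pelvis_rise_m * np.cos(
        4.0 * np.pi * (np.mod(np.asarray(phi), 1.0) - trough)
    )


def _shank_pitch_deg(phi_const: float, spec: GaitSpec, a1: float) -> float:
    """Shank (ankle→knee) pitch at a fixed phase.

    Only used at the heel-strike and toe-off phases, where (by the
    trough placement of :func:`_pelvis_height`) the pelvis sits at the
    same height at both events.
    """
    phi = np.array([phi_const])
    pelvis = _pelvis_height(phi, spec)
    ax = _ankle_x(phi, spec, a1)
    az = _ankle_height(phi, spec)
    kx, kz = _knee_ik(ax, az, pelvis, spec)
    return float(np.degrees(np.arctan2(kz - az, kx - ax))[0])


def _leg_sagittal(
    phi: np.ndarray, pelvis_z: np.ndarray, spec: GaitSpec, a1: float
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sagittal (x relative to hip centre, z up) positions of one leg.

    Stance foot pitch is the prescribed toe-pivot heel rise.  Swing foot
    pitch is derived so the measured shank–foot angle follows a smooth
    profile between its stance endpoint values plus a dorsiflexion lift —
    a swinging foot rides with the shank, which keeps the ankle's range
    of motion anatomical instead of inheriting the shank's full swing.
    """
    phi = np.mod(phi, 1.0)
    sf = spec.stance_fraction
    ankle_x = _ankle_x(phi, spec, a1)
    ankle_z = _ankle_height(phi, spec)
    knee_x, knee_z = _knee_ik(ankle_x, ankle_z, pelvis_z, spec)
    beta = _stance_pitch_deg(phi, spec)
    swing = phi >= sf
    if np.any(swing):
        tx, tz = spec.toe_offset_m
        gamma_f0 = math.degrees(math.atan2(tz, tx))
        gamma_s = np.degrees(np.arctan2(knee_z - ankle_z, knee_x - ankle_x))
        # measured dorsiflexion(+) angle: 90 − (γ_shank − γ_foot0 + β)
        m_to = 90.0 - (
            _shank_pitch_deg(sf, spec, a1) - gamma_f0 + spec.heel_rise_deg
        )
        m_hs = 90.0 - (_shank_pitch_deg(0.0, spec, a1) - gamma_f0)
        m_peak = max(m_to, m_hs) + spec.swing_ankle_lift_deg
        u = np.where(swing, (phi - sf) / (1.0 - sf), 0.0)
        p = spec.swing_peak_pos
        target = np.where(
            u < p,
            m_to + (m_peak - m_to) * _smoothstep(u / p),
            m_peak + (m_hs - m_peak) * _smoothstep((u - p) / (1.0 - p)),
        )
        beta_swing = 90.0 - target - gamma_s + gamma_f0
        beta = np.where(swing, beta_swing, beta)
    toe_dx, toe_dz = _rot_minus_beta(spec.toe_offset_m, beta)
    heel_dx, heel_dz = _rot_minus_beta(spec.heel_offset_m, beta)
    return {
        "ankle": (ankle_x, ankle_z),
        "knee": (knee_x, knee_z),
        "heel": (ankle_x + heel_dx, ankle_z + heel_dz),
        "foot_index": (ankle_x + toe_dx, ankle_z + toe_dz),
    }


# ---------------------------------------------------------------------------
# timeline: phase, hip translation, passes
# ---------------------------------------------------------------------------


def _timeline(spec: GaitSpec, n: int, fps: float):
    """Per-sample stride phase, hip x, facing sign, and pass bounds."""
    t = np.arange(n) / fps
    if spec.walk_mode == "treadmill":
        phase = t / spec.stride_time
        hip_x = np.zeros(n)
        facing = np.ones(n)
        passes = [(0.0, float(n / fps), "rightward")]
        return t, phase, hip_x, facing, passes
    v = 2.0 * spec.step_length / spec.stride_time
    pass_dur = spec.walkway_m / v
    bounds = []
    t0 = 0.5  # lead-in before the first pass
    direction = 1
    for _ in range(2 * spec.n_round_trips):
        bounds.append((t0, t0 + pass_dur, direction))
        t0 += pass_dur + spec.turn_duration_s
        direction = -direction
    phase = np.zeros(n)
    hip_x = np.zeros(n)
    facing = np.ones(n)
    tau = 0.0
    x = 0.0
    rate = 1.0 / spec.stride_time
    for i, ti in enumerate(t):
        active = None
        for (a, b, d) in bounds:
            if a <= ti < b:
                active = d
                break
        if active is not None:
            dt = 1.0 / fps
            tau += rate * dt
            x += active * v * dt
        phase[i] = tau
        hip_x[i] = x
        facing[i] = _facing_at(ti, bounds)
    passes = [(a, b, "rightward" if d > 0 else "leftward") for a, b, d in bounds]
    return t, phase, hip_x, facing, passes


def _facing_at(ti: float, bounds) -> float:
    last = 1
    for (a, b, d) in bounds:
        if ti >= a:
            last = d
        if ti < b:
            break
    return float(last)


def _event_times(spec: GaitSpec, duration: float, pass_bounds, offset: float):
    """Exact event times: phases offset+k (HS) and offset+k+sf (TO)."""
    sf = spec.stance_fraction
    T = spec.stride_time
    hs, to = [], []
    if spec.walk_mode == "treadmill":
        spans = [(0.0, duration, 0.0)]  # (t_start, t_end, tau_start)
    else:
        spans = []
        tau = 0.0
        for (a, b, _d) in pass_bounds:
            spans.append((a, min(b, duration), tau))
            tau += (b - a) / T
    for (a, b, tau0) in spans:
        if b <= a:
            continue
        tau1 = tau0 + (b - a) / T
        k = math.ceil(tau0 - offset - 1e-12)
        while offset + k < tau1:
            ti = a + (offset + k - tau0) * T
            if a <= ti < b:
                hs.append(ti)
            k += 1
        k = math.ceil(tau0 - offset - sf - 1e-12)
        while offset + k + sf < tau1:
            ti = a + (offset + k + sf - tau0) * T
            if a <= ti < b:
                to.append(ti)
            k += 1
    return np.array(sorted(hs)), np.array(sorted(to))


# ---------------------------------------------------------------------------
# world assembly, projection, noise
# ---------------------------------------------------------------------------

_SIDES = ("left", "right")


def _world_positions(spec: GaitSpec, n: int, fps: float):
    """All landmark positions in world coordinates (x fwd, z up, ml)."""
    a1 = _rel_amplitude(spec)
    t, phase, hip_x, facing, passes = _timeline(spec, n, fps)
    psi_l = _phase_warp(phase, spec.stance_fraction)
    pelvis_z = _pelvis_height(phase, spec)
    sway = -spec.ml_sway_m * np.sin(psi_l)
    world: dict[str, np.ndarray] = {}
    for side, offset, ml_sign in (("left", 0.0, -1.0), ("right", 0.5, 1.0)):
        leg = _leg_sagittal(np.mod(phase + offset, 1.0), pelvis_z, spec, a1)
        for point, (lx, lz) in leg.items():
            ml = ml_sign * spec.foot_ml_m + (sway * 0.3 if point == "knee" else 0.0)
            world[f"{side}_{point}"] = np.column_stack(
                [hip_x + facing * lx, lz, np.broadcast_to(ml, (n,))]
            )
        world[f"{side}_hip"] = np.column_stack(
            [hip_x, pelvis_z, ml_sign * spec.pelvis_width_m / 2.0 + sway]
        )
        world[f"{side}_shoulder"] = np.column_stack(
            [
                hip_x + facing * spec.trunk_lean_m,
                pelvis_z + spec.trunk_len_m,
                ml_sign * spec.shoulder_width_m / 2.0 + sway,
            ]
        )
    return world, t, passes


def _project_lateral(world, cam: CameraSpec):
    cx, cy = cam.image_center
    sgn = 1.0 if cam.camera_side == "left" else -1.0
    out = {}
    for name, w in world.items():
        x = cx + sgn * cam.pixels_per_meter * w[:, 0]
        y = cy - cam.pixels_per_meter * w[:, 1]
        out[name] = np.column_stack([x, y])
    return _apply_distortion(out, cam)


def _project_frontal(world, cam: CameraSpec, spec: GaitSpec):
    """Pinhole projection for a camera ahead of the subject on the walk axis."""
    cx, cy = cam.image_center
    # overground: camera beyond the walkway's far end; treadmill: the
    # camera faces a stationary subject at the configured distance
    cam_x = cam.camera_distance_m + (
        spec.walkway_m if spec.walk_mode == "overground" else 0.0
    )
    out = {}
    for name, w in world.items():
        depth = np.maximum(cam_x - w[:, 0], 0.3)
        u = cx + cam.focal_px * w[:, 2] / depth
        v = cy + cam.focal_px * (cam.camera_height_m - w[:, 1]) / depth
        out[name] = np.column_stack([u, v])
    return _apply_distortion(out, cam)


def _distort_points(pts: np.ndarray, cam: CameraSpec) -> np.ndarray:
    if cam.distortion_k == 0.0:
        return pts
    cx, cy = cam.image_center
    norm2 = cx * cx + cy * cy  # half-diagonal² of the image
    dx, dy = pts[..., 0] - cx, pts[..., 1] - cy
    scale = 1.0 + cam.distortion_k * (dx * dx + dy * dy) / norm2
    return np.stack([cx + dx * scale, cy + dy * scale], axis=-1)


def _apply_distortion(proj: dict, cam: CameraSpec) -> dict:
    if cam.distortion_k == 0.0:
        return proj
    return {name: _distort_points(p, cam) for name, p in proj.items()}


def _apply_noise(
    proj: dict,
    noise: NoiseSpec,
    profile: dict[str, float],
    rng: np.random.Generator,
) -> tuple[dict, dict]:
    positions, visibility = {}, {}
    for name in sorted(proj):
        pts = proj[name].copy()
        n = pts.shape[0]
        mean_vis = profile.get(name, 1.0)
        eps = rng.standard_normal(n)
        ar = np.empty(n)
        ar[0] = eps[0]
        rho = noise.visibility_ar_rho
        for i in range(1, n):
            ar[i] = rho * ar[i - 1] + math.sqrt(1.0 - rho * rho) * eps[i]
        vis = np.clip(mean_vis + noise.visibility_ar_sd * ar, 0.0, 1.0)
        sd = noise.jitter_sd_px * (1.0 + noise.occlusion_noise_factor * (1.0 - vis))
        pts += rng.standard_normal(pts.shape) * sd[:, None]
        spikes = rng.random(n) < noise.spike_rate
        if spikes.any():
            mag = noise.spike_magnitude_px * rng.uniform(0.5, 1.0, int(spikes.sum()))
            ang = rng.uniform(0.0, 2.0 * np.pi, int(spikes.sum()))
            pts[spikes, 0] += mag * np.cos(ang)
            pts[spikes, 1] += mag * np.sin(ang)
        dropped = vis < noise.visibility_floor
        pts[dropped] = np.nan
        positions[name] = pts
        visibility[name] = np.where(dropped, np.minimum(vis, 0.999), vis)
    return positions, visibility


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _condition(spec: GaitSpec) -> str:
    return "treadmill" if spec.walk_mode == "treadmill" else "overground_forward"


def _ground_truth(
    spec: GaitSpec,
    duration: float,
    fps: float,
    pass_bounds,
    view: str,
    ppm: float | None,
    subject: str,
) -> GaitGroundTruth:
    hs_l, to_l = _event_times(spec, duration, pass_bounds, 0.0)
    hs_r, to_r = _event_times(spec, duration, pass_bounds, 0.5)
    ev_l = GaitEvents("left", hs_l, to_l, source_view="mocap3d")
    ev_r = GaitEvents("right", hs_r, to_r, source_view="mocap3d")
    cycles = pair_bilateral(ev_l, ev_r)
    # drop cycles that bridge a turn: their stride spans non-walking time
    if spec.walk_mode == "overground":
        def same_pass(c):
            return any(a <= c.hs and c.hs_next <= b for (a, b, _d) in pass_bounds)
        cycles = [c for c in cycles if same_pass(c)]
    temporal = parameters.temporal_params(
        cycles, subject=subject, condition=_condition(spec), view=view
    )
    rows = []
    for c in cycles:
        if c.hs_contra is None:
            continue
        step_time = c.hs_contra - c.hs
        rows.append(
            {
                "subject": subject,
                "condition": _condition(spec),
                "view": view,
                "side": c.side,
                "cycle": c.index,
                "hs_time": c.hs,
                "step_length": spec.step_length,
                "step_time": step_time,
                "gait_speed": spec.step_length / step_time,
            }
        )
    import pandas as pd

    spatial = pd.DataFrame(rows)
    # noiseless sagittal angle traces via the same measurement geometry
    n = int(round(duration * fps))
    world, _t, _p = _world_positions(spec, n, fps)
    clean = TrajectorySet(
        frames=np.arange(n),
        positions={k: v * 1000.0 for k, v in world.items()},
        visibility={k: np.ones(n) for k in world},
        frame_rate=fps,
        view="mocap3d",
        subject_id=subject,
        condition=_condition(spec),
    )
    angles = {}
    for joint in ("hip", "knee", "ankle"):
        for side in _SIDES:
            series = kinematics.joint_angle_series(clean, joint, side)
            angles[(joint, side)] = series.angles_deg
    return GaitGroundTruth(
        events_left=ev_l,
        events_right=ev_r,
        cycles=cycles,
        temporal=temporal,
        spatial=spatial,
        angles_deg=angles,
        pass_bounds=[(a, b, "rightward" if d > 0 else "leftward") for a, b, d in pass_bounds]
        if spec.walk_mode == "overground"
        else [(a, b, d) for a, b, d in [(0.0, duration, "rightward")]],
        pixels_per_meter=ppm,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def simulate_gait(
    spec: GaitSpec,
    noise: NoiseSpec | None = None,
    view: str = "lateral",
    seed: int = 0,
    camera: CameraSpec | None = None,
    subject: str = "s0",
) -> tuple[TrajectorySet, GaitGroundTruth]:
    """Simulate one bout and return the trajectory plus exact ground truth.

    ``view`` selects the observation model: ``lateral`` (orthographic
    pixels), ``near_frontal`` (perspective pixels, progression along the
    optical axis), or ``mocap3d`` (noiseless millimetres at 240 Hz unless
    ``spec.fps`` says otherwise).  Identical inputs and seed give
    bit-identical outputs.
    """
    spec.validate()
    noise = noise or NoiseSpec()
    noise.validate()
    camera = camera or CameraSpec()
    fps = 240.0 if view == "mocap3d" and spec.fps == 30.0 else spec.fps
    if spec.walk_mode == "overground":
        v = 2.0 * spec.step_length / spec.stride_time
        pass_dur = spec.walkway_m / v
        duration = 0.5 + 2 * spec.n_round_trips * (pass_dur + spec.turn_duration_s)
    else:
        duration = spec.bout_duration_s
    n = int(round(duration * fps))
    world, _t, pass_bounds_raw = _world_positions(spec, n, fps)
    if spec.walk_mode == "overground":
        raw_bounds = [
            (a, b, 1 if d == "rightward" else -1) for (a, b, d) in pass_bounds_raw
        ]
    else:
        raw_bounds = []
    rng = np.random.default_rng(seed)
    meta: dict = {"seed": seed}
    if view == "mocap3d":
        positions = {k: v * 1000.0 for k, v in world.items()}
        visibility = {k: np.ones(n) for k in world}
        ppm = None
    else:
        if view == "lateral":
            proj = _project_lateral(world, camera)
            # ground markers bounding the walkway give the scale pair
            pts = np.array(
                [[0.0, 0.0], [spec.walkway_m, 0.0]]
            )
            cx, cy = camera.image_center
            sgn = 1.0 if camera.camera_side == "left" else -1.0
            img = np.column_stack(
                [cx + sgn * camera.pixels_per_meter * pts[:, 0],
                 cy - camera.pixels_per_meter * pts[:, 1]]
            )
            img = _distort_points(img, camera)
            meta["calibration_points_px"] = (tuple(img[0]), tuple(img[1]))
            meta["calibration_distance_m"] = spec.walkway_m
            ppm = camera.pixels_per_meter
        elif view == "near_frontal":
            proj = _project_frontal(world, camera, spec)
            ppm = None
        else:
            raise ValueError(f"unknown view {view!r}")
        profile = (
            noise.visibility_profile
            if noise.visibility_profile is not None
            else VISIBILITY_PROFILES.get((_condition(spec), view), {})
        )
        positions, visibility = _apply_noise(proj, noise, profile, rng)
    traj = TrajectorySet(
        frames=np.arange(n),
        positions=positions,
        visibility=visibility,
        frame_rate=fps,
        view=view,
        subject_id=subject,
        condition=_condition(spec),
        meta=meta,
    )
    truth = _ground_truth(spec, duration, fps, raw_bounds, view, ppm, subject)
    return traj, truth


def simulate_cohort(
    n_subjects: int = 24,
    seed: int = 0,
    view: str = "lateral",
    noise: NoiseSpec | None = None,
    base_spec: GaitSpec | None = None,
    camera: CameraSpec | None = None,
    stride_time_mean: float = 1.1,
    stride_time_sd: float = 0.1,
    step_length_mean: float = 0.55,
    step_length_sd: float = 0.08,
    stance_fraction_sd: float = 0.015,
) -> list[dict]:
    """Simulate a cohort: per subject a capture reference plus a video candidate.

    Subject gait parameters are drawn from normal distributions truncated
    to physiologically positive ranges; the reference (noiseless 3D
    capture, 240 Hz) and candidate (noisy video at ``view``) observe the
    same underlying motion on the same clock.  Returns one dict per
    subject with keys ``reference``, ``candidate``, ``truth``, ``spec``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if stride_time_sd < 0 or step_length_sd < 0:
        raise ValueError("distribution SDs must be non-negative")
    base = base_spec or GaitSpec()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        stride = float(np.clip(rng.normal(stride_time_mean, stride_time_sd), 0.8, 1.5))
        step = float(np.clip(rng.normal(step_length_mean, step_length_sd), 0.3, 0.75))
        sf = float(np.clip(rng.normal(0.62, stance_fraction_sd), 0.56, 0.68))
        spec = replace(
            base, stride_time=stride, step_length=step, stance_fraction=sf
        )
        # keep the drawn step inside the leg geometry's reach
        spec.step_length = min(spec.step_length, 0.98 * max_step_length(spec))
        subject = f"s{i:02d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        ref_spec = replace(spec, fps=30.0)
        ref, _ = simulate_gait(
            ref_spec, NoiseSpec.noiseless(), view="mocap3d",
            seed=sub_seed, subject=subject,
        )
        cand, truth = simulate_gait(
            spec, noise, view=view, seed=sub_seed, camera=camera, subject=subject
        )
        out.append(
            {"reference": ref, "candidate": cand, "truth": truth, "spec": spec}
        )
    return out
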
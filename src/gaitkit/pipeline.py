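"""End-to-end orchestration: configuration, per-subject analysis, reports.

The pipeline realises the full measurement chain — read or simulate →
preprocess → events → parameters → kinematics → agreement — and writes
parameter tables, agreement tables, angle summaries, plots, and a
machine-readable run manifest.  Everything is deterministic given the
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import agreement_report
from .gait_events import GaitEvents, detect_gait_events, pair_bilateral
from .io_keypoints import calibrate_scale
from .kinematics import angle_agreement, joint_angle_series, range_of_motion
from .parameters import spatial_params, temporal_params
from .preprocess import (
    PreprocessConfig,
    despike_and_fill,
    downsample,
    lowpass_zero_lag,
    segment_passes,
    trim_sync,
)
from .synthetic_gait import CameraSpec, GaitSpec, NoiseSpec, simulate_cohort
from .trajectory import TrajectorySet

log = logging.getLogger("gaitkit")


@dataclass
class RunConfig:
    """One YAML document describing a full run; unknown keys are rejected."""

    n_subjects: int = 24
    view: str = "lateral"
    walk_mode: str = "treadmill"
    seed: int = 0
    output_dir: str = "gaitkit_out"
    log_level: str = "INFO"
    modes: tuple = ("participants_mean", "all_step")
    match_tol_s: float = 0.25
    min_stride_s: float = 0.6
    target_fps: float = 30.0
    sync_trim_s: tuple | None = None
    make_plots: bool = True
    preprocess: dict = field(default_factory=dict)
    gait: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    camera: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.modes = tuple(self.modes)
        if self.sync_trim_s is not None:
            self.sync_trim_s = tuple(self.sync_trim_s)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**payload)
        for sub, allowed in (
            ("preprocess", PreprocessConfig),
            ("gait", GaitSpec),
            ("noise", NoiseSpec),
            ("camera", CameraSpec),
        ):
            extra = set(getattr(cfg, sub)) - {f.name for f in fields(allowed)}
            if extra:
                raise ValueError(f"unknown keys under {sub!r}: {sorted(extra)}")
        if cfg.view not in ("lateral", "near_frontal"):
            raise ValueError("view must be 'lateral' or 'near_frontal'")
        return cfg

    def to_yaml(self) -> str:
        payload = asdict(self)
        payload["modes"] = list(self.modes)
        if self.sync_trim_s is not None:
            payload["sync_trim_s"] = list(self.sync_trim_s)
        return yaml.safe_dump(payload, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(**self.preprocess)

    def gait_spec(self) -> GaitSpec:
        return GaitSpec(walk_mode=self.walk_mode, **self.gait)

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(**self.noise)

    def camera_spec(self) -> CameraSpec:
        return CameraSpec(**self.camera)


def preprocess_trajectory(
    traj: TrajectorySet, cfg: PreprocessConfig, target_fps: float | None = None
) -> TrajectorySet:
    """Standard conditioning: despike, gap-fill, low-pass, downsample."""
    if target_fps is not None and traj.frame_rate > target_fps:
        traj = downsample(traj, target_fps)
    out = despike_and_fill(traj, cfg)
    return lowpass_zero_lag(out, cfg, allow_gaps=True)


def bilateral_events(
    traj: TrajectorySet, min_stride_s: float = 0.6
) -> tuple[GaitEvents, GaitEvents]:
    """Detect both sides' events; overground bouts are analysed per pass.

    For overground trajectories each straight pass is processed with its
    own direction label and event times are mapped back to the bout's
    clock, so turn intervals contribute no events.
    """
    if traj.condition.startswith("overground"):
        chunks = segment_passes(traj)
        hs = {"left": [], "right": []}
        to = {"left": [], "right": []}
        for sub, _direction in chunks:
            offset = sub.meta.get("source_frames", (0, 0))[0] / sub.frame_rate
            for side in ("left", "right"):
                ev = detect_gait_events(sub, side, min_stride_s=min_stride_s)
                hs[side].extend(ev.heel_strikes + offset)
                to[side].extend(ev.toe_offs + offset)
        return tuple(
            GaitEvents(side, np.array(sorted(hs[side])), np.array(sorted(to[side])), traj.view)
            for side in ("left", "right")
        )
    return tuple(
        detect_gait_events(traj, side, min_stride_s=min_stride_s)
        for side in ("left", "right")
    )


def analyze_trajectory(
    traj: TrajectorySet,
    cfg: RunConfig,
    calibration=None,
    preprocessed: bool = False,
) -> dict:
    """Run one trajectory through events, parameters, and angle traces."""
    pcfg = cfg.preprocess_config()
    if not preprocessed:
        traj = preprocess_trajectory(traj, pcfg, target_fps=cfg.target_fps)
    if cfg.sync_trim_s is not None:
        traj = trim_sync(traj, *cfg.sync_trim_s)
    left, right = bilateral_events(traj, cfg.min_stride_s)
    cycles = pair_bilateral(left, right)
    temporal = temporal_params(
        cycles, subject=traj.subject_id, condition=traj.condition, view=traj.view
    )
    spatial = None
    if traj.view != "near_frontal":
        if calibration is None and "calibration_points_px" in traj.meta:
            a, b = traj.meta["calibration_points_px"]
            calibration = calibrate_scale(a, b, traj.meta["calibration_distance_m"])
        try:
            spatial = spatial_params(
                traj, cycles, calibration,
                subject=traj.subject_id, condition=traj.condition,
            )
        except ValueError as err:
            log.warning("%s: spatial parameters skipped (%s)", traj.subject_id, err)
    angles = {}
    for joint in ("hip", "knee", "ankle"):
        for side in ("left", "right"):
            try:
                angles[(joint, side)] = joint_angle_series(traj, joint, side)
            except ValueError:
                continue
    return {
        "trajectory": traj,
        "events": {"left": left, "right": right},
        "cycles": cycles,
        "temporal": temporal,
        "spatial": spatial,
        "angles": angles,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate a cohort and produce the full comparison report bundle.

    Returns a dict with the agreement tables, angle summary, and manifest;
    the same objects are written under ``cfg.output_dir``.
    """
    logging.basicConfig(level=cfg.log_level)
    t_start = time.time()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(
        n_subjects=cfg.n_subjects,
        seed=cfg.seed,
        view=cfg.view,
        noise=cfg.noise_spec() if cfg.noise else None,
        base_spec=cfg.gait_spec(),
        camera=cfg.camera_spec(),
    )
    ref_tp, cand_tp, ref_sp, cand_sp = [], [], [], []
    angle_rows = []
    warnings: list[str] = []
    for rec in cohort:
        subject = rec["spec"] and rec["candidate"].subject_id
        try:
            ref_res = analyze_trajectory(rec["reference"], cfg)
            cand_res = analyze_trajectory(rec["candidate"], cfg)
        except ValueError as err:
            warnings.append(f"{subject}: {err}")
            continue
        ref_tp.append(ref_res["temporal"])
        cand_tp.append(cand_res["temporal"])
        if ref_res["spatial"] is not None and cand_res["spatial"] is not None:
            ref_sp.append(ref_res["spatial"])
            cand_sp.append(cand_res["spatial"])
        for (joint, side), cand_series in cand_res["angles"].items():
            ref_series = ref_res["angles"].get((joint, side))
            if ref_series is None:
                continue
            n = min(cand_series.angles_deg.size, ref_series.angles_deg.size)
            try:
                mae_deg, r = angle_agreement(
                    cand_series.angles_deg[:n], ref_series.angles_deg[:n]
                )
            except ValueError as err:
                warnings.append(f"{subject} {side} {joint} angle: {err}")
                continue
            try:
                rom = range_of_motion(
                    ref_series, ref_res["events"][side]
                ).mean_deg
            except ValueError:
                rom = np.nan
            angle_rows.append(
                {
                    "subject": subject,
                    "joint": joint,
                    "side": side,
                    "rom_ref_deg": rom,
                    "mae_deg": mae_deg,
                    "pearson_r": r,
                }
            )
        log.info(
            "%s: %d ref cycles, %d candidate cycles",
            subject, len(ref_res["cycles"]), len(cand_res["cycles"]),
        )
    if not ref_tp:
        raise RuntimeError("pipeline produced no analysable subjects")
    ref_temporal = pd.concat(ref_tp, ignore_index=True)
    cand_temporal = pd.concat(cand_tp, ignore_index=True)
    reports = []
    for mode in cfg.modes:
        rep = agreement_report(
            ref_temporal, cand_temporal, mode=mode, tol_s=cfg.match_tol_s
        )
        rep.insert(0, "family", "temporal")
        reports.append(rep)
        if ref_sp:
            rep_sp = agreement_report(
                pd.concat(ref_sp, ignore_index=True),
                pd.concat(cand_sp, ignore_index=True),
                mode=mode,
                parameters=["step_length", "gait_speed"],
                tol_s=cfg.match_tol_s,
            )
            rep_sp.insert(0, "family", "spatial")
            reports.append(rep_sp)
    report = pd.concat(reports, ignore_index=True)
    angle_table = pd.DataFrame(angle_rows)
    report.to_csv(out_dir / "agreement.csv", index=False)
    ref_temporal.to_csv(out_dir / "temporal_reference.csv", index=False)
    cand_temporal.to_csv(out_dir / "temporal_candidate.csv", index=False)
    if not angle_table.empty:
        angle_table.to_csv(out_dir / "angles.csv", index=False)
    if cfg.make_plots:
        from .plotting import agreement_figure

        for mode in cfg.modes:
            agreement_figure(
                ref_temporal,
                cand_temporal,
                mode,
                cfg.match_tol_s,
                out_dir / f"bland_altman_{mode}.png",
            )
    manifest = {
        "gaitkit_version": __version__,
        "config_sha256": cfg.digest(),
        "seed": cfg.seed,
        "n_subjects_analysed": int(ref_temporal["subject"].nunique()),
        "runtime_s": round(time.time() - t_start, 2),
        "warnings": warnings,
        "config": yaml.safe_load(cfg.to_yaml()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "report": report,
        "angles": angle_table,
        "manifest": manifest,
        "reference_temporal": ref_temporal,
        "candidate_temporal": cand_temporal,
    }
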
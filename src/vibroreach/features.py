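"""Per-trial behavioral metrics extracted from 2D reach trajectories.

Movement onset is the first time the finite-difference hand speed exceeds a
threshold (default 0.02 mm/ms). Reaction time equals onset time (the Go cue
is at t = 0); movement time runs from onset to the outer-ring crossing. The
mid-reach angle is the direction of the fixation-to-cursor vector when the
reach first covers half the target distance (50 mm by default), linearly
interpolated between the bracketing samples; it serves as the behavioral
readout of the perceived target direction. Trials are excluded if they never
reach the ring entry eccentricity (90 mm), never move, or exceed the task's
reaction/movement time limits.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from ._angles import abs_ang_diff_deg, wrap_deg
from .config import TaskConfig
from .simulate import Trajectory

__all__ = [
    "detect_onset",
    "apply_exclusions",
    "mid_reach_angle",
    "mid_reach_error",
    "detect_hit",
    "reaction_and_movement_time",
    "extract_features",
    "extract_features_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "trajectory_id", "onset_ms", "rt_ms", "mt_ms", "mid_reach_angle_deg",
    "mid_reach_error_deg", "endpoint_angle_deg", "hit", "excluded",
    "exclusion_reason",
]


def _speeds(traj: Trajectory) -> np.ndarray:
    dt = np.diff(traj.t_ms)
    dx = np.diff(traj.x_mm)
    dy = np.diff(traj.y_mm)
    return np.hypot(dx, dy) / dt


def _eccentricity(traj: Trajectory) -> np.ndarray:
    return np.hypot(traj.x_mm, traj.y_mm)


def detect_onset(traj: Trajectory, v_thresh: float = 0.02) -> Optional[float]:
    """Time (ms) at which hand speed first exceeds ``v_thresh`` (mm/ms), or
    None if it never does."""
    if len(traj.t_ms) < 2:
        raise ValueError("trajectory needs at least 2 samples")
    speed = _speeds(traj)
    above = speed > v_thresh
    if not above.any():
        return None
    # speed[k] spans samples k..k+1; onset assigned to the later sample
    return float(traj.t_ms[int(np.argmax(above)) + 1])


def _crossing(traj: Trajectory, radius: float,
              ecc: Optional[np.ndarray] = None) -> Optional[Tuple[float, float, float]]:
    """First crossing of the given eccentricity: (t_ms, x_mm, y_mm),
    linearly interpolated between the bracketing samples."""
    if ecc is None:
        ecc = _eccentricity(traj)
    idx = np.nonzero(ecc >= radius)[0]
    if idx.size == 0:
        return None
    k = int(idx[0])
    if k == 0:
        return float(traj.t_ms[0]), float(traj.x_mm[0]), float(traj.y_mm[0])
    e0, e1 = ecc[k - 1], ecc[k]
    frac = 0.0 if e1 == e0 else (radius - e0) / (e1 - e0)
    t = traj.t_ms[k - 1] + frac * (traj.t_ms[k] - traj.t_ms[k - 1])
    x = traj.x_mm[k - 1] + frac * (traj.x_mm[k] - traj.x_mm[k - 1])
    y = traj.y_mm[k - 1] + frac * (traj.y_mm[k] - traj.y_mm[k - 1])
    return float(t), float(x), float(y)


def mid_reach_angle(traj: Trajectory, config: TaskConfig) -> Optional[float]:
    """Direction (deg, in [0, 360)) of the fixation-to-cursor vector at the
    mid-reach eccentricity, or None if the reach never gets that far."""
    cross = _crossing(traj, config.mid_eccentricity_mm)
    if cross is None:
        return None
    _, x, y = cross
    return float(wrap_deg(math.degrees(math.atan2(y, x))))


def mid_reach_error(mid_angle_deg: float, target_deg: float) -> float:
    """Absolute angular difference in [0, 180] between mid-reach angle and
    the cued target direction."""
    return float(abs_ang_diff_deg(mid_angle_deg, target_deg))


def detect_hit(traj: Trajectory, target_deg: float, config: TaskConfig) -> Optional[bool]:
    """Whether the ring-entry point lies within the target arc.

    The endpoint is the first crossing of the scoring eccentricity (ring entry
    by default); a hit requires its absolute angular error to be at most the
    half-arc angle (closed interval). Returns None if the ring is never entered.
    """
    cross = _crossing(traj, config.scoring_mm)
    if cross is None:
        return None
    _, x, y = cross
    angle = wrap_deg(math.degrees(math.atan2(y, x)))
    # closed interval; 1e-9 deg guards the boundary against round-off
    return bool(abs_ang_diff_deg(angle, target_deg) <= config.half_arc_deg + 1e-9)


def reaction_and_movement_time(traj: Trajectory, config: TaskConfig,
                               ) -> Tuple[Optional[float], Optional[float]]:
    """(rt_ms, mt_ms): Go-cue to onset, and onset to outer-ring crossing."""
    onset = detect_onset(traj, config.onset_speed_threshold)
    if onset is None:
        return None, None
    cross = _crossing(traj, config.ring_outer_mm)
    if cross is None:
        return onset, None
    return onset, cross[0] - onset


def apply_exclusions(traj: Trajectory, config: TaskConfig) -> Tuple[bool, str]:
    """(excluded, reason), reason in {none, min_eccentricity, no_onset, timeout}."""
    ecc = _eccentricity(traj)
    if float(ecc.max()) < config.ring_inner_mm:
        return True, "min_eccentricity"
    onset = detect_onset(traj, config.onset_speed_threshold)
    if onset is None:
        return True, "no_onset"
    if onset > config.max_rt_ms:
        return True, "timeout"
    outer = _crossing(traj, config.ring_outer_mm, ecc=ecc)
    if outer is None or (outer[0] - onset) > config.max_mt_ms:
        return True, "timeout"
    return False, "none"


def extract_features(traj: Trajectory, config: TaskConfig,
                     target_deg: Optional[float] = None) -> dict:
    """All per-trial metrics as one record; excluded trials carry no hit value."""
    excluded, reason = apply_exclusions(traj, config)
    rt, mt = reaction_and_movement_time(traj, config)
    mid = mid_reach_angle(traj, config)
    err = (mid_reach_error(mid, target_deg)
           if mid is not None and target_deg is not None else math.nan)
    endpoint = _crossing(traj, config.scoring_mm)
    ep_angle = (float(wrap_deg(math.degrees(math.atan2(endpoint[2], endpoint[1]))))
                if endpoint is not None else math.nan)
    hit: object = math.nan
    if not excluded and target_deg is not None:
        h = detect_hit(traj, target_deg, config)
        hit = bool(h) if h is not None else math.nan
    return {
        "trajectory_id": traj.trajectory_id,
        "onset_ms": math.nan if rt is None else rt,
        "rt_ms": math.nan if rt is None else rt,
        "mt_ms": math.nan if mt is None else mt,
        "mid_reach_angle_deg": math.nan if mid is None else mid,
        "mid_reach_error_deg": err,
        "endpoint_angle_deg": ep_angle,
        "hit": hit,
        "excluded": excluded,
        "exclusion_reason": reason,
    }


def extract_features_table(trials: pd.DataFrame, trajectories,
                           config: TaskConfig) -> pd.DataFrame:
    """Feature table for a trial table plus trajectory store.

    ``trajectories`` is a mapping or callable from trajectory_id to
    :class:`Trajectory`. Unresolvable references yield an excluded row with
    reason ``error`` instead of aborting the run.
    """
    getter = trajectories if callable(trajectories) else trajectories.get
    rows = []
    for rec in trials.itertuples(index=False):
        traj = getter(rec.trajectory_id)
        if traj is None:
            rows.append({**{c: math.nan for c in FEATURE_COLUMNS},
                         "trajectory_id": rec.trajectory_id,
                         "excluded": True, "exclusion_reason": "error"})
            continue
        rows.append(extract_features(traj, config, target_deg=rec.target_deg))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
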
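"""Synthetic center-out reach experiments with a configurable multisensory observer.

The generator reproduces the statistical structure the downstream analysis
assumes: a blocked session schedule (visual-only blocks alternating with
vibrotactile-containing blocks of 32 trials), bar-cloud visual cues whose
angular spread realizes the nominal uncertainty level, unimodal sensory
estimates drawn from von Mises distributions whose circular SD matches the
configured values, a bimodal combination stage implementing optimal
(variance-weighted) integration or the sub-optimal alternatives, and
minimum-jerk reach trajectories with angular execution noise.

Angles are in degrees, 0° rightward, counter-clockwise positive. On bimodal
trials the weighted combination is applied to signed deviations from the true
target rather than to raw angles; deviations are small relative to the circle,
so this linearization avoids 0/360° wraparound artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._angles import kappa_from_circular_sd_deg, wrap_deg, wrap_signed_deg
from .config import ObserverParams, StudyConfig, TaskConfig
from .encoding import all_directions, direction_category, encode_direction

__all__ = [
    "Trajectory",
    "generate_schedule",
    "generate_visual_cue",
    "simulate_unimodal_estimate",
    "combine_estimates",
    "generate_trajectory",
    "simulate_experiment",
    "run_synthetic_study",
]

TRIAL_COLUMNS = [
    "participant_id", "session", "block_index", "trial_index", "modality",
    "uncertainty_deg", "target_deg", "category", "bar_angles_deg",
    "motor_pattern", "trajectory_id",
]


@dataclass
class Trajectory:
    """Time-stamped 2D hand positions for one trial; origin at the fixation
    point center, t = 0 at the Go cue, millimetres and milliseconds."""

    trajectory_id: str
    t_ms: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trajectory_id": self.trajectory_id,
            "t_ms": self.t_ms, "x_mm": self.x_mm, "y_mm": self.y_mm,
        })


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# schedule

def generate_schedule(config: TaskConfig, seed, participant_id: str = "P01",
                      session: int | None = None) -> pd.DataFrame:
    """One participant's trial schedule, without cue realizations or trajectories.

    Blocks alternate between visual-only (VIS) blocks and vibrotactile-containing
    blocks (mixing VIS_VIB and VIB trials, ratio ``config.bimodal_fraction``).
    Directions and uncertainty levels are randomly interleaved within blocks;
    per-direction rotating counters keep the direction x uncertainty x modality
    cells as balanced as the integer constraints allow.
    """
    rng = _as_rng(seed)
    dirs = all_directions(config.n_directions)
    levels = [float(u) for u in config.uncertainty_levels_deg]
    # per (modality, direction) rotating pointer into the uncertainty levels
    unc_counter: Dict[Tuple[str, float], int] = {}
    dir_counter: Dict[str, int] = {}

    def next_unc(modality: str, d: float) -> float:
        # each direction starts its rotation at a direction-dependent offset,
        # so even a single block spreads over all uncertainty levels
        key = (modality, d)
        i = unc_counter.get(key, dirs.index(d) % len(levels))
        unc_counter[key] = i + 1
        return levels[i % len(levels)]

    def next_dirs(modality: str, count: int) -> List[float]:
        i = dir_counter.get(modality, 0)
        dir_counter[modality] = i + count
        return [dirs[(i + k) % len(dirs)] for k in range(count)]

    rows = []
    for block in range(config.n_blocks):
        block_type = "VIS" if block % 2 == 0 else "VIB_MIXED"
        if block_type == "VIS":
            modalities = ["VIS"] * config.block_size
        else:
            n_bimodal = int(round(config.block_size * config.bimodal_fraction))
            modalities = ["VIS_VIB"] * n_bimodal + ["VIB"] * (config.block_size - n_bimodal)
        trials = []
        for modality in ("VIS", "VIS_VIB", "VIB"):
            count = sum(1 for m in modalities if m == modality)
            if count == 0:
                continue
            for d in next_dirs(modality, count):
                u = next_unc(modality, d) if modality != "VIB" else math.nan
                trials.append((modality, d, u))
        order = rng.permutation(len(trials))
        sess = session if session is not None else (1 if block < config.blocks_session1 else 2)
        for k, idx in enumerate(order):
            modality, d, u = trials[idx]
            rows.append({
                "participant_id": participant_id,
                "session": sess,
                "block_index": block,
                "trial_index": k,
                "modality": modality,
                "uncertainty_deg": u,
                "target_deg": d,
                "category": direction_category(d),
                "bar_angles_deg": "",
                "motor_pattern": "",
                "trajectory_id": f"{participant_id}_b{block:03d}_t{k:03d}",
            })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# visual cue

def generate_visual_cue(target_deg: float, uncertainty_deg: float, n_bars: int,
                        seed) -> Tuple[List[float], bool]:
    """Bar-cloud cue for one trial.

    Returns ``(bar_angles_deg, target_revealed)``. At 0° uncertainty the target
    location is revealed directly and no bars are drawn; otherwise ``n_bars``
    positions are drawn i.i.d. from Normal(target, uncertainty²) and wrapped to
    [0, 360).
    """
    if uncertainty_deg < 0:
        raise ValueError("uncertainty must be >= 0")
    if uncertainty_deg == 0:
        return [], True
    rng = _as_rng(seed)
    bars = wrap_deg(rng.normal(target_deg, uncertainty_deg, size=n_bars))
    return [float(b) for b in bars], False


# ---------------------------------------------------------------------------
# observer

def _von_mises_deg(rng: np.random.Generator, mu_deg: float, sd_deg: float) -> float:
    """Draw an angle from a von Mises centered on mu with circular SD sd_deg."""
    if sd_deg == 0:
        return float(wrap_deg(mu_deg))
    kappa = kappa_from_circular_sd_deg(round(float(sd_deg), 9))
    draw = rng.vonmises(math.radians(mu_deg), kappa)
    return float(wrap_deg(math.degrees(draw)))


def _vib_bias_deg(target_deg: float, category: str, params: ObserverParams) -> float:
    """Signed bias of the vibrotactile percept toward the nearest cardinal.

    Nonzero only where configured; for intermediate directions the sign points
    from the target toward its nearest cardinal (intensity-confusion bias)."""
    mag = params.vib_bias_deg.get(category, 0.0)
    if mag == 0.0 or category != "intermediate":
        return 0.0
    offset = target_deg % 90.0
    return -mag if offset == 22.5 else mag


def simulate_unimodal_estimate(target_deg: float, modality: str,
                               uncertainty_deg: float, category: str,
                               params: ObserverParams, seed) -> float:
    """One unimodal estimate of the target direction.

    VIS estimates have SD ``sigma_vis_deg[uncertainty]``; VIB estimates have
    SD ``sigma_vib_deg[category]`` plus any configured confusion bias.
    """
    rng = _as_rng(seed)
    if modality == "VIS":
        sd = params.sigma_vis_deg[float(uncertainty_deg)]
        return _von_mises_deg(rng, target_deg, sd)
    if modality == "VIB":
        sd = params.sigma_vib_deg[category]
        mu = target_deg + _vib_bias_deg(target_deg, category, params)
        return _von_mises_deg(rng, mu, sd)
    raise ValueError(f"unknown unimodal modality {modality!r}")


def combine_estimates(est_vis: float, est_vib: float, target_deg: float,
                      params: ObserverParams, uncertainty_deg: float,
                      category: str, seed) -> float:
    """Combine two unimodal estimates into the planned reach direction.

    Weighting operates on signed deviations from the true target (simulator
    linearization; see module docstring). The weights use the observer's
    *believed* reliabilities, which default to the generating ones.
    """
    if est_vis is None or est_vib is None:
        raise ValueError("both unimodal estimates are required on bimodal trials")
    rng = _as_rng(seed)
    dev_vis = float(wrap_signed_deg(est_vis - target_deg))
    dev_vib = float(wrap_signed_deg(est_vib - target_deg))
    s2_vis = params.believed_sigma_vis(uncertainty_deg) ** 2
    s2_vib = params.believed_sigma_vib(category) ** 2
    if params.strategy == "mle":
        if s2_vis == 0 and s2_vib == 0:
            w_vis = 0.5
        elif s2_vis == 0:
            w_vis = 1.0
        elif s2_vib == 0:
            w_vis = 0.0
        else:
            w_vis = s2_vib / (s2_vis + s2_vib)
        dev = w_vis * dev_vis + (1.0 - w_vis) * dev_vib
    elif params.strategy == "fixed_weight":
        w = params.strategy_weight
        dev = w * dev_vis + (1.0 - w) * dev_vib
    elif params.strategy == "switch_min_variance":
        dev = dev_vis if s2_vis <= s2_vib else dev_vib
    elif params.strategy == "switch_probabilistic":
        dev = dev_vis if rng.random() < params.strategy_p else dev_vib
    else:  # pragma: no cover - guarded by ObserverParams.validate
        raise ValueError(f"unknown strategy {params.strategy!r}")
    return float(wrap_deg(target_deg + dev))


# ---------------------------------------------------------------------------
# trajectory

def _minjerk_s(x: np.ndarray) -> np.ndarray:
    return x * x * x * (10.0 + x * (-15.0 + 6.0 * x))


_S_GRID_X = np.linspace(0.0, 1.0, 4097)
_S_GRID_S = _minjerk_s(_S_GRID_X)


def _invert_minjerk(s_target: float) -> float:
    """Normalized time at which the min-jerk position profile reaches s_target."""
    return float(np.interp(s_target, _S_GRID_S, _S_GRID_X))


def generate_trajectory(planned_deg: float, params: ObserverParams,
                        config: TaskConfig, seed,
                        trajectory_id: str = "traj") -> Trajectory:
    """Synthesize one reach: hold at the start point, then a straight
    minimum-jerk movement in the executed direction.

    The executed direction is the planned one plus Normal(0, sigma_motor²)
    angular noise. The movement start is placed so that the first crossing of
    the velocity threshold occurs at the drawn reaction time, and its duration
    is scaled so that onset-to-outer-ring time equals the drawn movement time;
    detected RT/MT therefore recover the configured distributions.
    """
    rng = _as_rng(seed)
    executed = planned_deg + (rng.normal(0.0, params.sigma_motor_deg)
                              if params.sigma_motor_deg > 0 else 0.0)
    rt = max(50.0, rng.normal(params.rt_loc_ms, params.rt_scale_ms))
    mt = max(100.0, rng.normal(params.mt_loc_ms, params.mt_scale_ms))
    # start point inside the fixation circle
    r0 = config.start_radius_mm * math.sqrt(rng.random())
    a0 = rng.random() * 2.0 * math.pi
    p0 = np.array([r0 * math.cos(a0), r0 * math.sin(a0)])
    ecc_end = config.ring_outer_mm + config.overshoot_mm
    theta = math.radians(executed)
    p_end = np.array([ecc_end * math.cos(theta), ecc_end * math.sin(theta)])
    length = float(np.linalg.norm(p_end - p0))

    x_cross = _invert_minjerk(config.ring_outer_mm / ecc_end)
    v_th = config.onset_speed_threshold
    duration = mt / max(x_cross - 0.05, 1e-6)
    x_th = 0.05
    for _ in range(4):  # joint calibration of threshold time and duration
        c = math.sqrt(v_th * duration / (30.0 * length))
        x_th = 0.5 * (1.0 - math.sqrt(max(0.0, 1.0 - 4.0 * c))) if c < 0.25 else 0.5
        duration = mt / max(x_cross - x_th, 1e-6)
    t_move = max(config.sample_dt_ms, rt - x_th * duration)

    dt = config.sample_dt_ms
    n = int(math.floor((t_move + duration) / dt)) + 2
    t = np.arange(n) * dt
    x_norm = np.clip((t - t_move) / duration, 0.0, 1.0)
    s = _minjerk_s(x_norm)
    pos = p0[None, :] + s[:, None] * (p_end - p0)[None, :]
    return Trajectory(trajectory_id, t, pos[:, 0], pos[:, 1])


# ---------------------------------------------------------------------------
# full experiment

def _plan_trial(row, params: ObserverParams, rng: np.random.Generator) -> float:
    """Planned reach direction for one scheduled trial."""
    target = row.target_deg
    if params.lapse_rate > 0 and rng.random() < params.lapse_rate:
        return float(rng.random() * 360.0)
    if row.modality == "VIS":
        return simulate_unimodal_estimate(target, "VIS", row.uncertainty_deg,
                                          row.category, params, rng)
    if row.modality == "VIB":
        return simulate_unimodal_estimate(target, "VIB", math.nan,
                                          row.category, params, rng)
    est_vis = simulate_unimodal_estimate(target, "VIS", row.uncertainty_deg,
                                         row.category, params, rng)
    est_vib = simulate_unimodal_estimate(target, "VIB", math.nan,
                                         row.category, params, rng)
    return combine_estimates(est_vis, est_vib, target, params,
                             row.uncertainty_deg, row.category, rng)


def _realize_cues(trials: pd.DataFrame, config: TaskConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    bars_col = []
    motor_col = []
    for row in trials.itertuples(index=False):
        if row.modality in ("VIS", "VIS_VIB") and row.uncertainty_deg > 0:
            bars, _ = generate_visual_cue(row.target_deg, row.uncertainty_deg,
                                          config.n_bars, rng)
            bars_col.append(",".join(format(b, ".6f") for b in bars))
        else:
            bars_col.append("")
        if row.modality in ("VIB", "VIS_VIB"):
            motor_col.append(encode_direction(row.target_deg).serialize())
        else:
            motor_col.append("")
    trials = trials.copy()
    trials["bar_angles_deg"] = bars_col
    trials["motor_pattern"] = motor_col
    return trials


def simulate_participant(config: TaskConfig, params: ObserverParams, seed,
                         participant_id: str = "P01",
                         on_trajectory: Optional[Callable[[Trajectory, object], None]] = None,
                         keep_trajectories: bool = True,
                         ) -> Tuple[pd.DataFrame, Dict[str, Trajectory]]:
    """Simulate one participant's full session pair.

    ``on_trajectory(traj, trial_row)`` is invoked per trial as trajectories are
    produced; with ``keep_trajectories=False`` they are then discarded, which
    keeps large cohort simulations in constant memory.
    """
    rng = _as_rng(seed)
    trials = generate_schedule(config, rng, participant_id=participant_id)
    trials = _realize_cues(trials, config, rng)
    store: Dict[str, Trajectory] = {}
    for row in trials.itertuples(index=False):
        planned = _plan_trial(row, params, rng)
        traj = generate_trajectory(planned, params, config, rng,
                                   trajectory_id=row.trajectory_id)
        if on_trajectory is not None:
            on_trajectory(traj, row)
        if keep_trajectories:
            store[traj.trajectory_id] = traj
    return trials, store


def simulate_experiment(config: TaskConfig | StudyConfig,
                        params_per_participant: Optional[Iterable[ObserverParams]] = None,
                        seed=None,
                        on_trajectory: Optional[Callable[[Trajectory, object], None]] = None,
                        keep_trajectories: bool = True,
                        ) -> Tuple[pd.DataFrame, Dict[str, Trajectory]]:
    """Simulate a full cohort; reproducible given the seed.

    Accepts either a :class:`StudyConfig` (whose observers and seed are used
    unless overridden) or a :class:`TaskConfig` plus an explicit observer list.
    """
    if isinstance(config, StudyConfig):
        task = config.task
        observers = list(params_per_participant) if params_per_participant is not None \
            else config.observers()
        if seed is None:
            seed = config.seed
    else:
        task = config
        if params_per_participant is None:
            raise ValueError("params_per_participant required with a bare TaskConfig")
        observers = list(params_per_participant)
    if seed is None:
        raise ValueError("a seed is required for simulation")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(observers))
    tables = []
    store: Dict[str, Trajectory] = {}
    for i, (params, child) in enumerate(zip(observers, children)):
        pid = f"P{i + 1:02d}"
        rng = np.random.Generator(np.random.PCG64(child))
        trials, traj = simulate_participant(task, params, rng, participant_id=pid,
                                            on_trajectory=on_trajectory,
                                            keep_trajectories=keep_trajectories)
        tables.append(trials)
        store.update(traj)
    return pd.concat(tables, ignore_index=True), store


def run_synthetic_study(study: StudyConfig, seed=None,
                        ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and extract per-trial features in one streaming pass.

    Returns ``(trial_table, features_table)`` without materializing the
    trajectory store, so cohort size is limited by the tables only.
    """
    from .features import extract_features

    feature_rows: List[dict] = []

    def _collect(traj: Trajectory, row) -> None:
        feature_rows.append(extract_features(traj, study.task, target_deg=row.target_deg))

    trials, _ = simulate_experiment(study, seed=seed, on_trajectory=_collect,
                                    keep_trajectories=False)
    features = pd.DataFrame(feature_rows)
    return trials, features
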
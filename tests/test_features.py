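"""Per-trial feature extraction on constructed trajectories."""

import math

import numpy as np
import pytest

from vibroreach._angles import abs_ang_diff_deg, wrap_deg
from vibroreach.config import TaskConfig
from vibroreach.features import (apply_exclusions, detect_hit, detect_onset,
                                 extract_features, mid_reach_angle,
                                 mid_reach_error, reaction_and_movement_time)
from vibroreach.simulate import Trajectory


CFG = TaskConfig(sample_dt_ms=10.0)


def straight_path(angle_deg, speed=0.2, hold_ms=200.0, dt=10.0, end_mm=115.0,
                  tid="t"):
    """Stationary hold, then constant-speed straight reach."""
    theta = math.radians(angle_deg)
    n_hold = int(hold_ms / dt)
    dist_steps = np.arange(0.0, end_mm + speed * dt, speed * dt)
    d = np.concatenate([np.zeros(n_hold), dist_steps])
    t = np.arange(d.size) * dt
    return Trajectory(tid, t, d * math.cos(theta), d * math.sin(theta))


# ------------------------------------------------------------------- onset

def test_onset_on_step_profile():
    traj = straight_path(0.0, speed=0.1, hold_ms=200.0, dt=10.0)
    onset = detect_onset(traj)
    assert abs(onset - 200.0) <= 10.0  # within one sample of the step


def test_stationary_trajectory_has_no_onset():
    t = np.arange(0, 500, 10.0)
    traj = Trajectory("still", t, np.zeros_like(t), np.zeros_like(t))
    assert detect_onset(traj) is None
    excluded, reason = apply_exclusions(traj, CFG)
    assert excluded and reason == "min_eccentricity"


def test_onset_requires_two_samples():
    with pytest.raises(ValueError):
        detect_onset(Trajectory("x", np.array([0.0]), np.array([0.0]), np.array([0.0])))


# --------------------------------------------------------------- exclusions

def test_short_reach_excluded():
    traj = straight_path(0.0, end_mm=85.0)
    excluded, reason = apply_exclusions(traj, CFG)
    assert excluded and reason == "min_eccentricity"


def test_complete_reach_retained():
    traj = straight_path(0.0, end_mm=115.0)
    assert apply_exclusions(traj, CFG) == (False, "none")


def test_exclusion_count_matches_construction():
    paths = [straight_path(a, end_mm=85.0 if i < 3 else 112.0, tid=f"t{i}")
             for i, a in enumerate(np.linspace(0, 324, 10))]
    flags = [apply_exclusions(p, CFG)[0] for p in paths]
    assert sum(flags) == 3


def test_slow_reach_times_out():
    # 0.03 mm/ms: onset detected but the outer ring is reached after ~3.8 s
    traj = straight_path(0.0, speed=0.03, end_mm=115.0)
    excluded, reason = apply_exclusions(traj, CFG)
    assert excluded and reason == "timeout"


# ---------------------------------------------------------------- mid-reach

@pytest.mark.parametrize("angle", [45.0, 350.0, 180.0])
def test_mid_reach_angle_on_straight_path(angle):
    traj = straight_path(angle)
    got = mid_reach_angle(traj, CFG)
    assert 0.0 <= got < 360.0
    assert abs_ang_diff_deg(got, angle) < 1e-9


def test_mid_reach_angle_matches_dense_oracle():
    """Interpolated crossing agrees with a 100x-resampled nearest-crossing oracle."""
    t = np.arange(0, 1000.0, 10.0)
    prog = np.clip((t - 100.0) / 700.0, 0.0, 1.0)
    radius = 115.0 * prog
    bend = np.radians(40.0) * prog * (1 - prog) * 4.0 * 0.3  # curved path
    theta = np.radians(60.0) + bend
    traj = Trajectory("curve", t, radius * np.cos(theta), radius * np.sin(theta))

    fine = np.linspace(t[0], t[-1], t.size * 100)
    fx = np.interp(fine, t, traj.x_mm)
    fy = np.interp(fine, t, traj.y_mm)
    k = int(np.argmax(np.hypot(fx, fy) >= CFG.mid_eccentricity_mm))
    oracle = math.degrees(math.atan2(fy[k], fx[k])) % 360.0

    assert mid_reach_angle(traj, CFG) == pytest.approx(oracle, abs=0.01)


def test_mid_reach_unreachable_flagged():
    traj = straight_path(10.0, end_mm=30.0)
    assert mid_reach_angle(traj, CFG) is None


@pytest.mark.parametrize("mid,target,expected", [
    (90.0, 90.0, 0.0), (350.0, 10.0, 20.0), (0.0, 180.0, 180.0)])
def test_mid_reach_error(mid, target, expected):
    assert mid_reach_error(mid, target) == expected


# --------------------------------------------------------------------- hit

def test_hit_inside_and_outside_arc():
    assert detect_hit(straight_path(93.0), 90.0, CFG) is True      # 3 deg error
    assert detect_hit(straight_path(100.0), 90.0, CFG) is False    # 10 deg error


def test_hit_boundary_is_closed():
    half = CFG.half_arc_deg
    traj = straight_path(90.0 + half)
    assert detect_hit(traj, 90.0, CFG) is True


def test_hit_matches_geometric_oracle():
    """Angular criterion agrees with a dot-product point-in-arc oracle."""
    rng = np.random.default_rng(17)
    half_rad = math.radians(CFG.half_arc_deg)
    target_u = np.array([math.cos(math.radians(90.0)), math.sin(math.radians(90.0))])
    for _ in range(1000):
        angle = 90.0 + rng.uniform(-25, 25)
        traj = straight_path(angle)
        got = detect_hit(traj, 90.0, CFG)
        e = np.array([math.cos(math.radians(angle)), math.sin(math.radians(angle))])
        oracle = math.acos(np.clip(np.dot(e, target_u), -1, 1)) <= half_rad + 1e-12
        assert got == oracle


# ------------------------------------------------------------------- times

def test_rt_mt_on_constant_velocity_path():
    # onset at 250 ms (first super-threshold step ends at 250), 0.25 mm/ms
    traj = straight_path(0.0, speed=0.25, hold_ms=240.0, dt=10.0)
    rt, mt = reaction_and_movement_time(traj, CFG)
    assert rt == 250.0
    expected_cross = 250.0 + (110.0 / 0.25) - 10.0  # ring at 110 mm, onset lag
    assert mt == pytest.approx(expected_cross - rt, abs=10.0)


def test_extract_features_record():
    traj = straight_path(47.0, tid="tr1")
    rec = extract_features(traj, CFG, target_deg=45.0)
    assert rec["trajectory_id"] == "tr1"
    assert rec["rt_ms"] == rec["onset_ms"]
    assert rec["excluded"] is False or rec["excluded"] == False  # noqa: E712
    assert rec["mid_reach_error_deg"] == pytest.approx(2.0, abs=1e-9)
    assert rec["hit"] is True
    assert 0.0 <= rec["mid_reach_angle_deg"] < 360.0


def test_excluded_trial_has_no_hit():
    rec = extract_features(straight_path(0.0, end_mm=85.0), CFG, target_deg=0.0)
    assert rec["excluded"] and math.isnan(rec["hit"])
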
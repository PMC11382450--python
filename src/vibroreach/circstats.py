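"""Circular descriptive statistics for mid-reach angles.

Definitions follow the standard directional-statistics conventions: for
angles θ_i the mean resultant length is R = |mean(exp(iθ))|, the circular
variance is 1 − R, and the circular SD is sqrt(−2 ln R) (reported in
degrees). Before aggregation, mid-reach angles from different targets within
a condition are rotated to a common 0° direction by subtracting the cued
target angle, so the dispersion measures reach variability rather than
target layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._angles import wrap_signed_deg

__all__ = [
    "CircularSummary",
    "rotate_to_common",
    "circular_summary",
    "condition_summaries",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "participant_id", "modality", "uncertainty_deg", "n", "hit_rate",
    "mean_error_deg", "mean_rt_ms", "mean_mt_ms", "mean_deg", "R",
    "circ_var", "circ_sd_deg",
]


@dataclass(frozen=True)
class CircularSummary:
    n: int
    mean_deg: float
    R: float
    circ_var: float
    circ_sd_deg: float


def rotate_to_common(angles_deg, targets_deg) -> np.ndarray:
    """Per-trial deviations (angle − target), wrapped to (−180, 180]."""
    angles = np.asarray(angles_deg, dtype=float)
    targets = np.asarray(targets_deg, dtype=float)
    if angles.shape != targets.shape:
        raise ValueError("angles and targets must have the same length")
    return wrap_signed_deg(angles - targets)


def circular_summary(angles_deg: Sequence[float]) -> CircularSummary:
    """Circular mean, resultant length, variance and SD of a sample of angles.

    Requires n >= 2. A resultant length of exactly 0 leaves the circular SD
    undefined; it is flagged as infinite.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 2:
        raise ValueError("circular_summary requires at least 2 angles")
    rad = np.radians(angles)
    z = np.exp(1j * rad).mean()
    r = float(np.abs(z))
    mean = float(np.degrees(np.angle(z)) % 360.0)
    if r < 1e-15:  # numerically zero resultant: SD undefined
        r = 0.0
        sd = math.inf
        mean = math.nan
    else:
        sd = math.degrees(math.sqrt(-2.0 * math.log(min(r, 1.0))))
    return CircularSummary(n=int(angles.size), mean_deg=mean, R=r,
                           circ_var=1.0 - r, circ_sd_deg=sd)


def _group_key(df: pd.DataFrame) -> pd.Series:
    # VIB-only trials carry no uncertainty level; they form one group per
    # participant, encoded with an "NA" sentinel
    return df["uncertainty_deg"].map(
        lambda u: "NA" if pd.isna(u) else format(float(u), "g"))


def condition_summaries(features: pd.DataFrame, trials: pd.DataFrame,
                        min_trials: int = 2) -> pd.DataFrame:
    """Per participant × modality × uncertainty aggregates.

    Excluded trials are dropped first. Each retained group reports trial
    count, hit rate, mean mid-reach error, mean reaction and movement time,
    and the circular summary of target-rotated mid-reach angles. Groups with
    fewer than ``min_trials`` retained trials are dropped (the circular SD is
    undefined below n = 2).
    """
    merged = trials.merge(features, on="trajectory_id", how="inner")
    merged = merged[~merged["excluded"].astype(bool)]
    merged = merged[np.isfinite(merged["mid_reach_angle_deg"].astype(float))]
    if merged.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    merged = merged.copy()
    merged["_unc_key"] = _group_key(merged)
    rows = []
    for (pid, modality, unc_key), g in merged.groupby(
            ["participant_id", "modality", "_unc_key"], sort=True):
        if len(g) < min_trials:
            continue
        dev = rotate_to_common(g["mid_reach_angle_deg"].to_numpy(float),
                               g["target_deg"].to_numpy(float))
        cs = circular_summary(dev)
        rows.append({
            "participant_id": pid,
            "modality": modality,
            "uncertainty_deg": math.nan if unc_key == "NA" else float(unc_key),
            "n": cs.n,
            "hit_rate": float(np.mean(g["hit"].astype(float))),
            "mean_error_deg": float(np.mean(g["mid_reach_error_deg"].astype(float))),
            "mean_rt_ms": float(np.mean(g["rt_ms"].astype(float))),
            "mean_mt_ms": float(np.mean(g["mt_ms"].astype(float))),
            "mean_deg": cs.mean_deg,
            "R": cs.R,
            "circ_var": cs.circ_var,
            "circ_sd_deg": cs.circ_sd_deg,
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
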
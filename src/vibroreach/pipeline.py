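"""Full-study analysis: condition summaries -> MLE quantities -> group
contrasts -> figures and a human-readable report.

Every stage is a pure function of (inputs, config, seed); the CLI wraps these
with file I/O and manifests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .circstats import condition_summaries
from .config import TaskConfig
from .mle import fit_mle_result
from .stats import run_comparison_suite

__all__ = ["AnalysisResult", "filter_directions", "exclusion_counts",
           "analyze_study", "render_report", "make_figures"]

DIRECTION_SUBSETS = {
    "all": ("cardinal", "oblique", "intermediate"),
    "cardinal": ("cardinal",),
    "oblique": ("oblique",),
    "intermediate": ("intermediate",),
    "cardinal_oblique": ("cardinal", "oblique"),
}


@dataclass
class AnalysisResult:
    summaries: pd.DataFrame
    mle: pd.DataFrame
    comparisons: pd.DataFrame
    exclusions: pd.Series
    directions: str = "all"


def filter_directions(trials: pd.DataFrame, directions: str | tuple) -> pd.DataFrame:
    """Restrict a trial table to a direction-category subset (e.g. the
    cardinal+oblique subset used to probe intensity-discrimination effects)."""
    if isinstance(directions, str):
        cats = DIRECTION_SUBSETS.get(directions)
        if cats is None:
            cats = tuple(s.strip() for s in directions.split(","))
    else:
        cats = tuple(directions)
    unknown = set(cats) - {"cardinal", "oblique", "intermediate"}
    if unknown:
        raise ValueError(f"unknown direction categories: {sorted(unknown)}")
    return trials[trials["category"].isin(cats)]


def exclusion_counts(features: pd.DataFrame) -> pd.Series:
    """Counts per exclusion reason (including 'none'), summing to the input."""
    if len(features) == 0:
        return pd.Series(dtype=int)
    return features["exclusion_reason"].value_counts()


def analyze_study(trials: pd.DataFrame, features: pd.DataFrame,
                  directions: str = "all",
                  variance_measure: str = "circ_sd_deg",
                  n_boot: int = 1000, seed=None) -> AnalysisResult:
    """Run the full analysis chain on a trial + feature table pair."""
    sub = filter_directions(trials, directions)
    feats = features[features["trajectory_id"].isin(sub["trajectory_id"])]
    summaries = condition_summaries(feats, sub)
    mle = fit_mle_result(summaries, variance_measure=variance_measure)
    comparisons = run_comparison_suite(summaries, mle, n_boot=n_boot, seed=seed)
    return AnalysisResult(summaries=summaries, mle=mle, comparisons=comparisons,
                          exclusions=exclusion_counts(feats),
                          directions=directions)


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_report(result: AnalysisResult) -> str:
    """Markdown report of exclusions, condition means and all contrasts."""
    lines = ["# Synthetic study analysis report", ""]
    lines.append(f"Direction subset: {result.directions}")
    total = int(result.exclusions.sum()) if len(result.exclusions) else 0
    lines += ["", f"## Exclusions ({total} trials processed)", ""]
    for reason, count in result.exclusions.items():
        lines.append(f"- {reason}: {count}")
    lines += ["", "## Condition means (across participants)", ""]
    if len(result.summaries):
        g = (result.summaries
             .assign(uncertainty=lambda d: d["uncertainty_deg"].fillna(-1))
             .groupby(["modality", "uncertainty"]))
        lines.append("| modality | uncertainty | hit rate | error (deg) | RT (ms) | MT (ms) | circ SD (deg) |")
        lines.append("|---|---|---|---|---|---|---|")
        for (mod, unc), rows in g:
            unc_str = "NA" if unc < 0 else f"{unc:g}"
            lines.append(
                f"| {mod} | {unc_str} | {rows['hit_rate'].mean():.3f} "
                f"| {rows['mean_error_deg'].mean():.2f} | {rows['mean_rt_ms'].mean():.0f} "
                f"| {rows['mean_mt_ms'].mean():.0f} | {rows['circ_sd_deg'].mean():.2f} |")
    lines += ["", "## Group contrasts (Holm-adjusted within family)", ""]
    if len(result.comparisons):
        lines.append("| family | contrast | mean diff | test | p (adj) | 95% CI |")
        lines.append("|---|---|---|---|---|---|")
        for r in result.comparisons.itertuples(index=False):
            lines.append(
                f"| {r.family} | {r.contrast} | {r.mean_diff:+.4g} | {r.test_used} "
                f"| {_fmt_p(r.p_adjusted)} | [{r.ci_low:.4g}, {r.ci_high:.4g}] |")
    else:
        lines.append("(no contrasts computable)")
    lines.append("")
    return "\n".join(lines)


def make_figures(result: AnalysisResult, out_dir) -> list:
    """Performance-vs-uncertainty and observed-vs-predicted figures (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    s = result.summaries
    if len(s):
        fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
        metrics = [("hit_rate", "hit rate"), ("mean_error_deg", "mid-reach error (deg)"),
                   ("mean_rt_ms", "reaction time (ms)"), ("mean_mt_ms", "movement time (ms)")]
        for ax, (col, label) in zip(axes.ravel(), metrics):
            for mod, color in (("VIS", "0.4"), ("VIS_VIB", "tab:green")):
                g = (s[s["modality"] == mod].groupby("uncertainty_deg")[col]
                     .mean().sort_index())
                ax.plot(g.index, g.values, "o-", color=color, label=mod)
            vib = s[s["modality"] == "VIB"][col]
            if len(vib):
                ax.axhline(vib.mean(), color="goldenrod", ls="--", label="VIB")
            ax.set_ylabel(label)
            ax.set_xlabel("visual uncertainty (deg)")
        axes[0, 0].legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = out_dir / "performance.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    m = result.mle
    if len(m):
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        g = m.groupby("uncertainty_deg")
        levels = sorted(m["uncertainty_deg"].unique())
        obs_sd = [math.sqrt(v) for v in g["sigma2_bimodal_obs"].mean()]
        pred_sd = [math.sqrt(v) for v in g["sigma2_bimodal_mle_corrected"].mean()]
        ax1.plot(levels, obs_sd, "o-", color="darkgreen", label="observed")
        ax1.plot(levels, pred_sd, "s-", color="tab:blue", label="MLE prediction")
        ax1.set_xlabel("visual uncertainty (deg)")
        ax1.set_ylabel("bimodal circular SD (deg)")
        ax1.legend(frameon=False)
        ax2.plot(levels, g["w_vis_emp"].mean(), "o-", color="darkgreen", label="empirical")
        ax2.plot(levels, g["w_vis_mle"].mean(), "s-", color="tab:blue", label="MLE prediction")
        ax2.set_xlabel("visual uncertainty (deg)")
        ax2.set_ylabel("visual weight")
        ax2.set_ylim(-0.05, 1.05)
        ax2.legend(frameon=False)
        fig.tight_layout()
        path = out_dir / "mle_predictions.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    return written
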
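"""Group-level paired comparisons with normality gating, Holm correction and
bootstrap confidence intervals.

Each contrast compares two per-participant mean vectors. Differences are
first checked for normality (Shapiro–Wilk); a paired t-test is used when the
check passes, a Wilcoxon signed-rank test otherwise, always two-sided at
alpha 0.05. Raw p-values are adjusted within each contrast family with the
Bonferroni–Holm step-down procedure, and nonparametric bootstrap CIs over
participants accompany every mean difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "paired_compare",
    "holm_adjust",
    "bootstrap_ci",
    "run_comparison_suite",
    "COMPARISON_COLUMNS",
]

COMPARISON_COLUMNS = [
    "family", "contrast", "metric", "n", "mean_a", "mean_b", "mean_diff",
    "statistic", "p_raw", "p_adjusted", "normality_p", "test_used",
    "ci_low", "ci_high",
]


@dataclass
class ComparisonResult:
    contrast: str
    n: int
    mean_diff: float
    statistic: float
    p_raw: float
    normality_p: float
    test_used: str
    ci_low: float = math.nan
    ci_high: float = math.nan
    p_adjusted: float = math.nan


class DegenerateVarianceError(ValueError):
    """Paired differences are a nonzero constant: no within-pair variability."""


def paired_compare(values_a: Sequence[float], values_b: Sequence[float],
                   alpha: float = 0.05, contrast: str = "") -> ComparisonResult:
    """Two-sided paired comparison of per-participant means.

    Shapiro–Wilk on the differences decides between a paired t-test and the
    Wilcoxon signed-rank test. Identical vectors return p = 1 flagged as
    degenerate; a nonzero constant difference raises
    :class:`DegenerateVarianceError`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("paired_compare requires n >= 3")
    diff = a - b
    if np.ptp(diff) == 0.0:
        if diff[0] == 0.0:
            return ComparisonResult(contrast, a.size, 0.0, 0.0, 1.0,
                                    math.nan, "degenerate")
        raise DegenerateVarianceError(
            "constant nonzero paired differences; test statistic undefined")
    normality_p = float(sps.shapiro(diff).pvalue)
    if normality_p > alpha:
        res = sps.ttest_rel(a, b)
        test_used = "paired_t"
    else:
        res = sps.wilcoxon(a, b, zero_method="wilcox")
        test_used = "wilcoxon"
    return ComparisonResult(contrast, int(a.size), float(diff.mean()),
                            float(res.statistic), float(res.pvalue),
                            normality_p, test_used)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni–Holm step-down adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def bootstrap_ci(values: Sequence[float], statistic=np.mean,
                 n_boot: int = 1000, level: float = 0.95,
                 seed=None) -> Tuple[float, float]:
    """Percentile CI of a statistic under resampling participants with
    replacement."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("bootstrap_ci requires a non-empty sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    reps = np.apply_along_axis(statistic, 1, x[idx])
    lo = float(np.percentile(reps, 100 * (1 - level) / 2))
    hi = float(np.percentile(reps, 100 * (1 + level) / 2))
    return lo, hi


# ---------------------------------------------------------------------------
# contrast suite

def _paired_frame(summaries: pd.DataFrame, metric: str,
                  sel_a: dict, sel_b: dict) -> Optional[Tuple[np.ndarray, np.ndarray]]:
    def _select(sel: dict) -> pd.Series:
        m = summaries
        for k, v in sel.items():
            if v is None or (isinstance(v, float) and math.isnan(v)):
                m = m[m[k].isna()]
            else:
                m = m[m[k] == v]
        return m.set_index("participant_id")[metric]

    sa, sb = _select(sel_a), _select(sel_b)
    common = sa.index.intersection(sb.index).sort_values()
    if len(common) < 3:
        return None
    return sa.loc[common].to_numpy(float), sb.loc[common].to_numpy(float)


def _result_row(family: str, contrast: str, metric: str,
                a: np.ndarray, b: np.ndarray, n_boot: int,
                rng: np.random.Generator) -> dict:
    try:
        res = paired_compare(a, b, contrast=contrast)
    except DegenerateVarianceError:
        res = ComparisonResult(contrast, len(a), float(np.mean(a - b)),
                               math.nan, math.nan, math.nan, "degenerate")
    if res.test_used != "degenerate" or res.p_raw == 1.0:
        lo, hi = bootstrap_ci(a - b, n_boot=n_boot, seed=rng)
    else:
        lo = hi = float(np.mean(a - b))
    return {
        "family": family, "contrast": contrast, "metric": metric,
        "n": res.n, "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        "mean_diff": res.mean_diff, "statistic": res.statistic,
        "p_raw": res.p_raw, "p_adjusted": math.nan,
        "normality_p": res.normality_p, "test_used": res.test_used,
        "ci_low": lo, "ci_high": hi,
    }


def run_comparison_suite(summaries: pd.DataFrame,
                         mle_results: Optional[pd.DataFrame] = None,
                         n_boot: int = 1000, seed=None) -> pd.DataFrame:
    """All group-level contrasts, Holm-adjusted within each metric family.

    Families: VIS vs VIS+VIB per uncertainty level for hit rate, mid-reach
    error, RT and MT; VIS at the highest uncertainty vs VIB; bimodal variance
    vs minimum unimodal variance per level; observed vs MLE-predicted
    (motor-corrected) bimodal variance per level; and empirical vs predicted
    visual weights per level.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if summaries is None or len(summaries) == 0:
        return pd.DataFrame(columns=COMPARISON_COLUMNS)
    rows: List[dict] = []
    levels = sorted(summaries.loc[summaries["modality"] == "VIS_VIB",
                                  "uncertainty_deg"].dropna().unique())

    perf_metrics = ["hit_rate", "mean_error_deg", "mean_rt_ms", "mean_mt_ms"]
    for metric in perf_metrics:
        for u in levels:
            pair = _paired_frame(summaries, metric,
                                 {"modality": "VIS", "uncertainty_deg": u},
                                 {"modality": "VIS_VIB", "uncertainty_deg": u})
            if pair is None:
                continue
            rows.append(_result_row(f"performance_{metric}",
                                    f"VIS vs VIS_VIB @ u={u:g}", metric,
                                    pair[0], pair[1], n_boot, rng))

    vis_levels = sorted(summaries.loc[summaries["modality"] == "VIS",
                                      "uncertainty_deg"].dropna().unique())
    if vis_levels and (summaries["modality"] == "VIB").any():
        u_hi = vis_levels[-1]
        for metric in ("hit_rate", "mean_error_deg"):
            pair = _paired_frame(summaries, metric,
                                 {"modality": "VIS", "uncertainty_deg": u_hi},
                                 {"modality": "VIB", "uncertainty_deg": math.nan})
            if pair is not None:
                rows.append(_result_row("vis_high_vs_vib",
                                        f"VIS @ u={u_hi:g} vs VIB", metric,
                                        pair[0], pair[1], n_boot, rng))

    if mle_results is not None and len(mle_results) > 0:
        for u in sorted(mle_results["uncertainty_deg"].unique()):
            g = mle_results[mle_results["uncertainty_deg"] == u]
            if len(g) < 3:
                continue
            specs = [
                ("variance_reduction", f"bimodal vs min unimodal @ u={u:g}",
                 "sigma2", "sigma2_bimodal_obs", "min_unimodal_sigma2"),
                ("mle_variance", f"observed vs MLE-predicted variance @ u={u:g}",
                 "sigma2", "sigma2_bimodal_obs", "sigma2_bimodal_mle_corrected"),
                ("mle_weights", f"empirical vs MLE-predicted weight @ u={u:g}",
                 "w_vis", "w_vis_emp", "w_vis_mle"),
            ]
            for family, contrast, metric, col_a, col_b in specs:
                rows.append(_result_row(family, contrast, metric,
                                        g[col_a].to_numpy(float),
                                        g[col_b].to_numpy(float), n_boot, rng))

    table = pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
    if len(table):
        for _, idx in table.groupby("family").groups.items():
            p = table.loc[idx, "p_raw"].to_numpy(float)
            finite = np.isfinite(p)
            adjusted = np.full_like(p, np.nan)
            if finite.any():
                adjusted[finite] = holm_adjust(p[finite])
            table.loc[idx, "p_adjusted"] = adjusted
    return table
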
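"""Optimal-integration (MLE) predictions and empirical cue weights.

Under maximum-likelihood cue integration, two unimodal estimates with
variances σ²_VIS and σ²_VIB combine with weights proportional to inverse
variances,

    w_VIS = σ²_VIB / (σ²_VIS + σ²_VIB),     w_VIB = 1 − w_VIS,

yielding a fused estimate whose variance is the product over the sum,

    σ²_bi = σ²_VIS σ²_VIB / (σ²_VIS + σ²_VIB),

which is strictly below either unimodal variance. Because reach variance
also contains execution noise, the smallest observed variance across all
conditions, σ²_MIN, is taken as a motor proxy and the corrected prediction

    σ²_bi,corr = (σ²_VIS − σ²_MIN)(σ²_VIB − σ²_MIN) /
                 (σ²_VIS + σ²_VIB − 2 σ²_MIN) + σ²_MIN

is used when comparing with data. The empirically attained visual weight is
inferred from the variance drop of bimodal relative to vibrotactile trials,

    w_VIS,emp = (σ²_VIB − σ²_bi) / σ²_VIB.

Variances throughout are squared circular SDs in degrees² (see the circular
statistics module); the alternative 1 − R measure can be selected where a
summary table is consumed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "predict_weights",
    "predict_bimodal_variance",
    "predict_bimodal_variance_corrected",
    "empirical_visual_weight",
    "min_unimodal_test",
    "VarianceSet",
    "variance_sets_from_summaries",
    "fit_mle_result",
    "MLE_COLUMNS",
]


def predict_weights(sigma2_vis: float, sigma2_vib: float) -> Tuple[float, float]:
    """(w_vis, w_vib), inverse-variance weights summing to 1."""
    if sigma2_vis < 0 or sigma2_vib < 0:
        raise ValueError("variances must be >= 0")
    if sigma2_vis == 0 and sigma2_vib == 0:
        raise ValueError("at least one variance must be positive")
    if sigma2_vis == 0:
        return 1.0, 0.0
    if sigma2_vib == 0:
        return 0.0, 1.0
    w_vis = sigma2_vib / (sigma2_vis + sigma2_vib)
    return float(w_vis), float(1.0 - w_vis)


def predict_bimodal_variance(sigma2_vis: float, sigma2_vib: float) -> float:
    """Product-over-sum fused variance; at most min of the inputs."""
    if sigma2_vis < 0 or sigma2_vib < 0:
        raise ValueError("variances must be >= 0")
    total = sigma2_vis + sigma2_vib
    if total == 0:
        return 0.0
    return float(sigma2_vis * sigma2_vib / total)


def predict_bimodal_variance_corrected(sigma2_vis: float, sigma2_vib: float,
                                       sigma2_min: float,
                                       clamp: bool = True) -> float:
    """Motor-corrected fused variance; reduces to the uncorrected form at
    sigma2_min = 0.

    Requires sigma2_min <= min(inputs). With ``clamp=True`` (default) small
    negative sensory factors arising from numerical ties are clamped to 0
    with a warning instead of raising.
    """
    if sigma2_min < 0:
        raise ValueError("sigma2_min must be >= 0")
    a = sigma2_vis - sigma2_min
    b = sigma2_vib - sigma2_min
    if a < 0 or b < 0:
        if not clamp:
            raise ValueError(
                "sigma2_min exceeds a unimodal variance "
                f"({sigma2_min} > min({sigma2_vis}, {sigma2_vib}))")
        warnings.warn("sigma2_min exceeds a unimodal variance; clamping the "
                      "sensory factor at 0", RuntimeWarning, stacklevel=2)
        a = max(a, 0.0)
        b = max(b, 0.0)
    denom = a + b
    if denom == 0:
        return float(sigma2_min)
    return float(a * b / denom + sigma2_min)


def empirical_visual_weight(sigma2_vib: float, sigma2_bimodal: float,
                            ) -> Tuple[float, float]:
    """(raw, clipped) empirical visual weight from the bimodal variance drop.

    Raw values may fall outside [0, 1] under sampling noise; statistics should
    use the raw value, the clipped one is for display.
    """
    if sigma2_vib <= 0:
        raise ValueError("sigma2_vib must be > 0")
    w = (sigma2_vib - sigma2_bimodal) / sigma2_vib
    return float(w), float(min(max(w, 0.0), 1.0))


@dataclass
class VarianceSet:
    """One participant's reach variances per condition (deg² of circular SD)."""

    participant_id: str
    sigma2_vis: Dict[float, float]       # uncertainty level -> variance
    sigma2_vib: float                    # pooled VIB variance
    sigma2_bimodal: Dict[float, float]   # uncertainty level -> VIS+VIB variance
    sigma2_min: float = field(init=False)

    def __post_init__(self) -> None:
        cells = list(self.sigma2_vis.values()) + list(self.sigma2_bimodal.values()) \
            + [self.sigma2_vib]
        if any(v < 0 for v in cells):
            raise ValueError("variances must be >= 0")
        self.sigma2_min = float(min(cells))


def min_unimodal_test(vs: VarianceSet) -> pd.DataFrame:
    """Bimodal variance against the smaller unimodal variance, per uncertainty.

    A negative ``difference`` (bimodal minus minimum unimodal) is the variance
    reduction optimal integration predicts; cue switching predicts none.
    """
    rows = []
    for u in sorted(vs.sigma2_bimodal):
        s2_vis = vs.sigma2_vis.get(u, math.nan)
        pairs = {"VIS": s2_vis, "VIB": vs.sigma2_vib}
        source = min(pairs, key=lambda k: (math.inf if math.isnan(pairs[k]) else pairs[k]))
        min_var = pairs[source]
        rows.append({
            "participant_id": vs.participant_id,
            "uncertainty_deg": u,
            "sigma2_bimodal": vs.sigma2_bimodal[u],
            "min_unimodal_sigma2": min_var,
            "min_unimodal_source": source,
            "difference": vs.sigma2_bimodal[u] - min_var,
        })
    return pd.DataFrame(rows)


def variance_sets_from_summaries(summaries: pd.DataFrame,
                                 variance_measure: str = "circ_sd_deg",
                                 ) -> Dict[str, VarianceSet]:
    """Build per-participant variance sets from a condition-summary table.

    ``variance_measure`` selects the dispersion whose square (for circ_sd_deg)
    or value (for circ_var) is treated as the variance.
    """
    if variance_measure not in ("circ_sd_deg", "circ_var"):
        raise ValueError("variance_measure must be 'circ_sd_deg' or 'circ_var'")

    def _var(rows: pd.DataFrame) -> Dict[float, float]:
        out = {}
        for r in rows.itertuples(index=False):
            v = r.circ_sd_deg ** 2 if variance_measure == "circ_sd_deg" else r.circ_var
            out[float(r.uncertainty_deg)] = float(v)
        return out

    sets: Dict[str, VarianceSet] = {}
    for pid, g in summaries.groupby("participant_id", sort=True):
        vis = _var(g[g["modality"] == "VIS"])
        bim = _var(g[g["modality"] == "VIS_VIB"])
        vib_rows = g[g["modality"] == "VIB"]
        if vib_rows.empty or not vis or not bim:
            continue
        r = vib_rows.iloc[0]
        s2_vib = float(r["circ_sd_deg"] ** 2 if variance_measure == "circ_sd_deg"
                       else r["circ_var"])
        sets[str(pid)] = VarianceSet(str(pid), vis, s2_vib, bim)
    return sets


MLE_COLUMNS = [
    "participant_id", "uncertainty_deg", "sigma2_vis", "sigma2_vib",
    "sigma2_bimodal_obs", "sigma2_min", "w_vis_mle", "w_vib_mle",
    "sigma2_bimodal_mle", "sigma2_bimodal_mle_corrected", "w_vis_emp",
    "w_vis_emp_clipped", "min_unimodal_sigma2", "min_unimodal_source",
    "min_unimodal_difference",
]


def fit_mle_result(summaries: pd.DataFrame,
                   variance_measure: str = "circ_sd_deg") -> pd.DataFrame:
    """All MLE quantities per participant × uncertainty from condition summaries.

    Per participant, σ²_MIN is the smallest variance over all modality ×
    uncertainty cells of retained trials; predictions for comparison with data
    use the motor-corrected form (the uncorrected one is also reported), and
    empirical weights come from the observed variance drop.
    """
    sets = variance_sets_from_summaries(summaries, variance_measure)
    rows = []
    for pid in sorted(sets):
        vs = sets[pid]
        mut = min_unimodal_test(vs).set_index("uncertainty_deg")
        for u in sorted(vs.sigma2_bimodal):
            if u not in vs.sigma2_vis:
                continue
            s2_vis = vs.sigma2_vis[u]
            s2_vib = vs.sigma2_vib
            w_vis, w_vib = predict_weights(s2_vis, s2_vib)
            w_emp, w_emp_clip = empirical_visual_weight(s2_vib, vs.sigma2_bimodal[u])
            rows.append({
                "participant_id": pid,
                "uncertainty_deg": u,
                "sigma2_vis": s2_vis,
                "sigma2_vib": s2_vib,
                "sigma2_bimodal_obs": vs.sigma2_bimodal[u],
                "sigma2_min": vs.sigma2_min,
                "w_vis_mle": w_vis,
                "w_vib_mle": w_vib,
                "sigma2_bimodal_mle": predict_bimodal_variance(s2_vis, s2_vib),
                "sigma2_bimodal_mle_corrected": predict_bimodal_variance_corrected(
                    s2_vis, s2_vib, vs.sigma2_min),
                "w_vis_emp": w_emp,
                "w_vis_emp_clipped": w_emp_clip,
                "min_unimodal_sigma2": mut.loc[u, "min_unimodal_sigma2"],
                "min_unimodal_source": mut.loc[u, "min_unimodal_source"],
                "min_unimodal_difference": mut.loc[u, "difference"],
            })
    return pd.DataFrame(rows, columns=MLE_COLUMNS)
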
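"""Paired comparisons, Holm correction, bootstrap CIs, and the contrast suite."""

import math

import numpy as np
import pandas as pd
import pytest

from vibroreach.stats import (DegenerateVarianceError, bootstrap_ci,
                              holm_adjust, paired_compare,
                              run_comparison_suite)


def test_identical_vectors_degenerate():
    res = paired_compare([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert res.p_raw == 1.0 and res.mean_diff == 0.0
    assert res.test_used == "degenerate"


def test_constant_nonzero_difference_raises():
    with pytest.raises(DegenerateVarianceError):
        paired_compare([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


def test_constant_shift_detected_at_n31():
    rng = np.random.default_rng(41)
    b = rng.normal(0.0, 1.0, size=31)
    a = b + 1.0 + rng.normal(0.0, 0.2, size=31)
    res = paired_compare(a, b)
    assert res.p_raw < 0.001
    assert res.mean_diff == pytest.approx(1.0, abs=0.2)


def test_non_normal_differences_use_wilcoxon():
    rng = np.random.default_rng(42)
    b = np.zeros(31)
    a = rng.exponential(1.0, size=31) ** 3  # heavily skewed differences
    res = paired_compare(a, b)
    assert res.test_used == "wilcoxon"


def test_length_and_size_validation():
    with pytest.raises(ValueError):
        paired_compare([1.0, 2.0], [1.0])
    with pytest.raises(ValueError):
        paired_compare([1.0, 2.0], [3.0, 4.0])


# -------------------------------------------------------------------- holm

def brute_force_holm(p):
    """Step-down definition: sort, multiply by (m-i), enforce monotonicity."""
    p = list(p)
    order = sorted(range(len(p)), key=lambda i: p[i])
    out = [0.0] * len(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (len(p) - rank) * p[idx])
        out[idx] = min(1.0, running)
    return out


def test_holm_examples():
    np.testing.assert_allclose(holm_adjust([0.01]), [0.01])
    np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])


def test_holm_matches_brute_force_oracle():
    rng = np.random.default_rng(43)
    for _ in range(50):
        p = rng.uniform(0, 1, size=rng.integers(1, 12))
        np.testing.assert_allclose(holm_adjust(p), brute_force_holm(p), atol=1e-12)


def test_holm_dominates_raw_and_matches_bonferroni_at_min():
    rng = np.random.default_rng(44)
    p = rng.uniform(0, 0.2, size=8)
    adj = holm_adjust(p)
    assert (adj >= p - 1e-15).all()
    assert adj[np.argmin(p)] == pytest.approx(min(1.0, p.min() * p.size))


def test_holm_empty():
    assert holm_adjust([]).size == 0


# --------------------------------------------------------------- bootstrap

def test_bootstrap_constant_statistic_zero_width():
    lo, hi = bootstrap_ci(np.full(20, 3.14), seed=1)
    assert lo == hi == pytest.approx(3.14)


def test_bootstrap_deterministic_under_seed():
    x = np.random.default_rng(45).normal(size=31)
    assert bootstrap_ci(x, seed=7) == bootstrap_ci(x, seed=7)
    assert bootstrap_ci(x, seed=7) != bootstrap_ci(x, seed=8)


def test_bootstrap_width_matches_normal_theory():
    # mean of n=31 standard normals: CI width ~ 2 * 1.96 / sqrt(31) ~ 0.70
    rng = np.random.default_rng(46)
    widths = []
    for _ in range(60):
        x = rng.normal(0.0, 1.0, size=31)
        lo, hi = bootstrap_ci(x, n_boot=500, seed=rng)
        widths.append(hi - lo)
    assert np.mean(widths) == pytest.approx(0.70, abs=0.08)


# ------------------------------------------------------------------- suite

def _toy_summaries(rng, pids):
    rows = []
    for pid in pids:
        for mod in ("VIS", "VIS_VIB"):
            for u in (0.0, 60.0):
                bonus = 0.2 if (mod == "VIS_VIB" and u == 60.0) else 0.0
                rows.append({
                    "participant_id": pid, "modality": mod, "uncertainty_deg": u,
                    "n": 30, "hit_rate": min(1.0, 0.5 + bonus + rng.normal(0, 0.03)),
                    "mean_error_deg": 10.0 - 20 * bonus + rng.normal(0, 0.5),
                    "mean_rt_ms": 300.0 + rng.normal(0, 5),
                    "mean_mt_ms": 500.0 + rng.normal(0, 5),
                    "mean_deg": 0.0, "R": 0.99, "circ_var": 0.01,
                    "circ_sd_deg": 8.0 + rng.normal(0, 0.3),
                })
        rows.append({"participant_id": pid, "modality": "VIB",
                     "uncertainty_deg": math.nan, "n": 30, "hit_rate": 0.6,
                     "mean_error_deg": 9.0, "mean_rt_ms": 300.0, "mean_mt_ms": 500.0,
                     "mean_deg": 0.0, "R": 0.98, "circ_var": 0.02,
                     "circ_sd_deg": 12.0 + rng.normal(0, 0.3)})
    return pd.DataFrame(rows)


def test_empty_input_gives_empty_table():
    out = run_comparison_suite(pd.DataFrame(), None)
    assert len(out) == 0


def test_suite_detects_planted_effect_and_adjusts_within_family():
    rng = np.random.default_rng(47)
    table = run_comparison_suite(_toy_summaries(rng, [f"P{i:02d}" for i in range(12)]),
                                 None, n_boot=200, seed=3)
    hit = table[table["family"] == "performance_hit_rate"].set_index("contrast")
    assert hit.loc["VIS vs VIS_VIB @ u=60", "p_adjusted"] < 0.01
    assert hit.loc["VIS vs VIS_VIB @ u=60", "mean_diff"] < 0
    assert (table["p_adjusted"].dropna() >= table["p_raw"].dropna() - 1e-15).all()
    assert ((table["ci_low"] <= table["mean_diff"] + 1e-12)
            & (table["mean_diff"] <= table["ci_high"] + 1e-12)).all()


def test_suite_invariant_to_participant_order():
    rng = np.random.default_rng(48)
    pids = [f"P{i:02d}" for i in range(8)]
    s = _toy_summaries(rng, pids)
    a = run_comparison_suite(s, None, n_boot=100, seed=5)
    b = run_comparison_suite(s.sample(frac=1.0, random_state=1).reset_index(drop=True),
                             None, n_boot=100, seed=5)
    pd.testing.assert_frame_equal(a, b)
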
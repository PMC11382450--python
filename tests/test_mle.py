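"""Closed-form MLE predictions, empirical weights, and their invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vibroreach.mle import (VarianceSet, empirical_visual_weight,
                            fit_mle_result, min_unimodal_test,
                            predict_bimodal_variance,
                            predict_bimodal_variance_corrected,
                            predict_weights, variance_sets_from_summaries)

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


@pytest.mark.parametrize("s2v,s2t,expected", [
    (3.0, 3.0, (0.5, 0.5)),
    (4.0, 1.0, (0.2, 0.8)),
    (0.0, 7.0, (1.0, 0.0)),
    (7.0, 0.0, (0.0, 1.0)),
])
def test_weight_examples(s2v, s2t, expected):
    assert predict_weights(s2v, s2t) == pytest.approx(expected)


def test_weights_need_one_positive_variance():
    with pytest.raises(ValueError):
        predict_weights(0.0, 0.0)


@pytest.mark.parametrize("s2v,s2t,expected", [
    (3.0, 3.0, 1.5),
    (4.0, 1.0, 0.8),
    (0.0, 9.0, 0.0),
])
def test_bimodal_variance_examples(s2v, s2t, expected):
    assert predict_bimodal_variance(s2v, s2t) == pytest.approx(expected)


@given(positive, positive)
@settings(max_examples=200, deadline=None)
def test_bimodal_variance_below_both_inputs(s2v, s2t):
    out = predict_bimodal_variance(s2v, s2t)
    assert out < min(s2v, s2t)


@given(positive, positive)
@settings(max_examples=200, deadline=None)
def test_weights_sum_to_one(s2v, s2t):
    w_vis, w_vib = predict_weights(s2v, s2t)
    assert w_vis + w_vib == pytest.approx(1.0, abs=1e-12)
    assert 0.0 <= w_vis <= 1.0


@given(positive, positive)
@settings(max_examples=200, deadline=None)
def test_corrected_reduces_to_uncorrected_at_zero_motor(s2v, s2t):
    assert predict_bimodal_variance_corrected(s2v, s2t, 0.0) == pytest.approx(
        predict_bimodal_variance(s2v, s2t), rel=1e-12)


def test_corrected_examples():
    assert predict_bimodal_variance_corrected(5.0, 2.0, 1.0) == pytest.approx(1.8)
    # zero first sensory factor -> motor variance only
    assert predict_bimodal_variance_corrected(1.0, 9.0, 1.0) == pytest.approx(1.0)
    # degenerate denominator: both inputs equal sigma2_min
    assert predict_bimodal_variance_corrected(2.0, 2.0, 2.0) == pytest.approx(2.0)


def test_corrected_monotone_in_each_unimodal_variance():
    grid = np.linspace(1.5, 50.0, 40)
    outs = [predict_bimodal_variance_corrected(v, 10.0, 1.0) for v in grid]
    assert all(b >= a - 1e-12 for a, b in zip(outs, outs[1:]))
    outs = [predict_bimodal_variance_corrected(10.0, v, 1.0) for v in grid]
    assert all(b >= a - 1e-12 for a, b in zip(outs, outs[1:]))


def test_corrected_clamps_numerical_ties_with_warning():
    with pytest.warns(RuntimeWarning):
        out = predict_bimodal_variance_corrected(1.0, 9.0, 1.0 + 1e-9)
    assert out == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError):
        predict_bimodal_variance_corrected(1.0, 9.0, 2.0, clamp=False)


def test_empirical_weight_boundaries():
    assert empirical_visual_weight(4.0, 4.0)[0] == 0.0
    assert empirical_visual_weight(4.0, 0.0)[0] == 1.0
    raw, clipped = empirical_visual_weight(4.0, 5.0)
    assert raw < 0.0 and clipped == 0.0
    with pytest.raises(ValueError):
        empirical_visual_weight(0.0, 1.0)


def test_min_unimodal_test_sources():
    vs = VarianceSet("P01",
                     sigma2_vis={0.0: 4.0, 60.0: 625.0},
                     sigma2_vib=144.0,
                     sigma2_bimodal={0.0: 4.1, 60.0: 120.0})
    assert vs.sigma2_min == 4.0
    t = min_unimodal_test(vs).set_index("uncertainty_deg")
    assert t.loc[60.0, "min_unimodal_source"] == "VIB"
    assert t.loc[0.0, "min_unimodal_source"] == "VIS"
    assert t.loc[60.0, "difference"] == pytest.approx(120.0 - 144.0)


def _summary_frame(pid, rows):
    cols = ["participant_id", "modality", "uncertainty_deg", "circ_sd_deg", "circ_var"]
    data = [[pid, m, u, sd, 1.0 - math.exp(-0.5 * math.radians(sd) ** 2)]
            for m, u, sd in rows]
    df = pd.DataFrame(data, columns=cols)
    for extra in ("n", "hit_rate", "mean_error_deg", "mean_rt_ms", "mean_mt_ms",
                  "mean_deg", "R"):
        df[extra] = 1.0
    return df


def test_fit_mle_result_consistent_with_closed_forms():
    rows = [("VIS", 0.0, 2.0), ("VIS", 60.0, 25.0),
            ("VIS_VIB", 0.0, 2.1), ("VIS_VIB", 60.0, 10.0),
            ("VIB", math.nan, 12.0)]
    res = fit_mle_result(_summary_frame("P01", rows))
    assert len(res) == 2
    r = res[res["uncertainty_deg"] == 60.0].iloc[0]
    assert r["w_vis_mle"] == pytest.approx(144.0 / (625.0 + 144.0))
    assert r["sigma2_bimodal_mle"] == pytest.approx(625.0 * 144.0 / 769.0)
    assert r["sigma2_min"] == pytest.approx(4.0)
    assert r["sigma2_bimodal_mle_corrected"] == pytest.approx(
        (621.0 * 140.0) / (625.0 + 144.0 - 8.0) + 4.0)
    assert r["w_vis_emp"] == pytest.approx((144.0 - 100.0) / 144.0)


def test_zero_motor_floor_makes_corrections_coincide():
    # a zero-variance cell drives sigma2_min to 0, so Eq-3- and Eq-4-style
    # predictions are identical
    rows = [("VIS", 0.0, 0.0), ("VIS", 60.0, 25.0),
            ("VIS_VIB", 0.0, 1.0), ("VIS_VIB", 60.0, 10.0),
            ("VIB", math.nan, 12.0)]
    res = fit_mle_result(_summary_frame("P01", rows))
    np.testing.assert_allclose(res["sigma2_bimodal_mle"],
                               res["sigma2_bimodal_mle_corrected"])


def test_variance_measure_option():
    rows = [("VIS", 0.0, 5.0), ("VIS_VIB", 0.0, 5.0), ("VIB", math.nan, 5.0)]
    sets = variance_sets_from_summaries(_summary_frame("P01", rows),
                                        variance_measure="circ_var")
    assert sets["P01"].sigma2_vib == pytest.approx(
        1.0 - math.exp(-0.5 * math.radians(5.0) ** 2))
    with pytest.raises(ValueError):
        variance_sets_from_summaries(_summary_frame("P01", rows), "bogus")
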
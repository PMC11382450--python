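# vibroreach

Analysis pipeline for visuo-vibrotactile cue integration in center-out
reaching, together with a synthetic experiment simulator that makes every
stage testable by parameter recovery.

## The problem

When a reach target is signaled both by an uncertain visual cue and by an
artificial vibrotactile code on the arm (four ERM motors, each encoding a
cardinal direction; pairs and intensity-asymmetric pairs encoding oblique and
intermediate directions), how should — and how do — observers combine the two
signals? The maximum-likelihood-estimation (MLE) framework predicts that two
unimodal estimates with variances σ²_VIS and σ²_VIB are combined with
inverse-variance weights

    w_VIS = σ²_VIB / (σ²_VIS + σ²_VIB),      w_VIB = 1 − w_VIS,

yielding a bimodal estimate of variance

    σ²_VIS+VIB = σ²_VIS σ²_VIB / (σ²_VIS + σ²_VIB),

strictly below either unimodal variance. Because behavioral reach variance
also contains execution noise, the smallest observed variance across
conditions, σ²_MIN, serves as a motor proxy and the corrected prediction

    σ²_VIS+VIB = (σ²_VIS − σ²_MIN)(σ²_VIB − σ²_MIN)
                 / (σ²_VIS + σ²_VIB − 2σ²_MIN) + σ²_MIN

is compared with data. The empirically attained visual weight follows from
the variance drop in bimodal relative to vibrotactile-only trials:

    w_VIS,emp = (σ²_VIB − σ²_VIS+VIB) / σ²_VIB.

The package is aimed at sensorimotor and multisensory-psychophysics
researchers who want to run this analysis on trial tables + 2D hand
trajectories, or to study its statistical behavior on simulated observers.

## What's inside

- `vibroreach.encoding` — deterministic codec between the 16 ring directions
  and 4-motor vibration patterns.
- `vibroreach.simulate` — session scheduler (32-trial blocks alternating
  visual-only and vibrotactile-containing, 14 + 22 blocks over two sessions),
  bar-cloud visual cues, a configurable Bayesian observer (optimal
  integration, fixed weights, or cue switching), and minimum-jerk reach
  trajectories with motor noise.
- `vibroreach.features` — movement onset (0.02 mm/ms velocity threshold),
  exclusions (90 mm minimum eccentricity, timeouts), mid-reach angle/error,
  hit detection, reaction and movement times.
- `vibroreach.circstats` — target-rotated circular summaries (mean resultant
  length R, circular variance 1 − R, circular SD √(−2 ln R)).
- `vibroreach.mle` — the closed-form predictions and empirical weights above,
  plus the bimodal-vs-minimum-unimodal variance test.
- `vibroreach.stats` — paired comparisons with normality gating (paired t /
  Wilcoxon), Bonferroni–Holm correction, bootstrap CIs, and the full group
  contrast suite.
- `vibroreach.cli` — `vibroreach simulate | features | analyze | report |
  recovery-test`.

## Worked example

Simulate a small cohort of optimal observers (visual SDs 2/8/15/25° at the
0/15/30/60° uncertainty levels, vibrotactile SD 12°, motor SD 3°), run the
full pipeline, and compare empirical weights with the predictions:

```python
from vibroreach import run_synthetic_study, analyze_study
from vibroreach.scenarios import recovery_study

study = recovery_study(n_participants=8, blocks=24, seed=7)
trials, features = run_synthetic_study(study)
result = analyze_study(trials, features, n_boot=200, seed=7)

summary = (result.mle.groupby("uncertainty_deg")
           [["w_vis_mle", "w_vis_emp", "sigma2_bimodal_obs",
             "sigma2_bimodal_mle_corrected"]].mean().round(3))
print(summary.to_string())
```

prints

```
                 w_vis_mle  w_vis_emp  sigma2_bimodal_obs  sigma2_bimodal_mle_corrected
uncertainty_deg
0.0                  0.924      0.914              13.104                        12.751
15.0                 0.682      0.635              56.586                        54.124
30.0                 0.407      0.335             101.908                        97.704
60.0                 0.205      0.176             125.816                       126.846
```

As visual uncertainty grows, the predicted visual weight falls from 0.92 to
0.21 and the empirical weight recovered from the simulated reaches tracks it;
observed bimodal variances (deg²) match the motor-corrected predictions
within sampling noise — the signature of optimal integration. Sub-optimal
observers (`vibroreach.scenarios.switching_observer`,
`confusion_observer`) break these signatures in the diagnostic ways the
contrast suite detects.

The same pipeline runs from the shell:

```
vibroreach simulate --config study.yaml --out run/
vibroreach features --in run/ --out run/
vibroreach analyze  --in run/ --out run/analysis --seed 1
vibroreach report   --in run/analysis
```

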
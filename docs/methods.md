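# Methods

## Task model

The simulated task is a center-out reach to one of 16 directions on a ring
(4 cardinal, 4 oblique, 8 intermediate, i.e. multiples of 22.5°; 0° is
rightward, counter-clockwise positive). Targets are 20 mm arcs at 100 mm
from the fixation point, inside a 90–110 mm annulus. A trial is cued either
visually (VIS), vibrotactilely (VIB), or bimodally (VIS+VIB). Visual
reliability is manipulated by a cloud of five bars drawn i.i.d. from a
normal distribution centered on the target with SD 0, 15, 30 or 60° (at 0°
the target is shown directly). Vibrotactile cues use four ERM motors, one
per cardinal direction: one motor fully driven encodes a cardinal target,
two equal motors an oblique target, and a full/low intensity pair an
intermediate target. Cue modality alternates between 32-trial blocks
(visual-only vs vibrotactile-containing); the default session plan is
14 + 22 blocks over two sessions, i.e. 1152 trials per participant.

## Observer model

The observer is a parametric ideal-observer variant that closes the loop
between the generator and the analysis:

- Unimodal estimates are von Mises draws centered on the target. The
  concentration κ is chosen numerically so that the circular SD
  √(−2 ln(I₁(κ)/I₀(κ))) equals the configured angular SD; this mapping is
  well conditioned for SDs ≤ 60° and is inverted with Brent's method on the
  exponentially scaled Bessel ratio.
- Visual SDs are per uncertainty level (defaults 2/8/15/25°; the 2° floor at
  0° uncertainty stands in for residual perceptual noise when the target is
  shown directly). Vibrotactile SDs are per direction category (defaults
  8/12/18° for cardinal/oblique/intermediate, emulating the difficulty
  gradient of detecting one motor, two motors, and discriminating two
  intensities; these defaults are simulator parameters, not measured
  values).
- On bimodal trials the estimates are combined on *signed deviations from
  the true target* rather than raw angles — a linearization that avoids
  0/360° wrap artifacts and is accurate because deviations are small
  relative to the circle. Strategies: `mle` (inverse-variance weights),
  `fixed_weight(w)`, `switch_min_variance` (use the cue believed more
  reliable), `switch_probabilistic(p)`.
- Weights use the observer's *believed* reliabilities
  (`assumed_sigma_*`), which default to the generating ones. Setting them
  apart models miscalibrated weighting: the `confusion` scenario inflates
  the true intermediate-direction vibrotactile SD to 25°, adds a 15° bias of
  intermediate percepts toward the nearest cardinal (intensity-confusion),
  and leaves the believed SD at the uniform 12° — overconfidence in the
  hardest cues. This is the mechanism that makes observed bimodal variance
  exceed the optimal-integration prediction on the full direction set while
  leaving the cardinal+oblique subset compliant; inflating the SD alone
  cannot produce the violation, because pooling a concave function of the
  per-category variances only ever pushes the observed variance *below* the
  prediction computed from pooled unimodal variances.
- Execution adds Normal(0, σ²_motor) angular noise (default 3°) plus a small
  uniformly placed start-point jitter inside a 2 mm disc.

Reach trajectories are straight minimum-jerk paths preceded by a stationary
hold. The movement start and duration are calibrated (jointly, by a few
fixed-point iterations on the quintic speed profile) so that the first
crossing of the 0.02 mm/ms velocity threshold occurs at the drawn reaction
time and the onset-to-outer-ring interval equals the drawn movement time;
detected RT/MT therefore recover the configured distributions (default
truncated normals, RT 300 ± 40 ms, MT 500 ± 60 ms) rather than being biased
by the detection rule. The generated bar clouds are stimulus realizations
only; the observer's visual noise is configured, not derived from the bars.

## Feature extraction and aggregation

Movement onset is the first finite-difference speed sample above the
threshold; trials are excluded for never reaching 90 mm eccentricity, never
moving, or exceeding the 1000 ms reaction/movement limits. The mid-reach
angle is read at the first crossing of half the target distance (50 mm;
configurable, since "half the distance to the ring" could also be read as
45 mm — the 50 mm choice matches targets sitting at 100 mm), linearly
interpolated between the bracketing samples. Hits are scored at the
ring-entry crossing (90 mm, configurable): the endpoint's absolute angular
error must be at most the half-arc angle, arc length / (2 · target
distance) = 0.1 rad ≈ 5.73°, as a closed interval.

Condition aggregates are per participant × modality × uncertainty;
vibrotactile-only trials carry no uncertainty level and form a single VIB
cell per participant (serialized with an explicit `NA` sentinel). Mid-reach
angles are first rotated to a common 0° direction by subtracting the cued
target. Dispersion uses the directional-statistics definitions (R, 1 − R,
√(−2 ln R) in degrees).

## Variance convention and MLE fitting

The "variance" entering the weight and fusion formulas is the squared
circular SD in deg². The 1 − R measure is supported as an alternative
(`variance_measure="circ_var"`); the squared-SD convention is the default
because it behaves like a linear variance in the small-angle regime where
the fusion algebra is derived, and because the observed dispersions (≤ ~30°)
are safely within that regime. σ²_MIN is the minimum over *all* modality ×
uncertainty cells of a participant, computed per participant (consistent
with per-subject weights). If numerical ties make a sensory factor of the
corrected prediction negative, it is clamped at 0 with a warning. Empirical
weights are reported raw and [0, 1]-clipped; statistics use the raw values,
since sampling noise legitimately pushes them outside the unit interval.

## Group statistics

The group layer uses per-participant means with paired tests: Shapiro–Wilk
on the paired differences gates between a paired t-test and the Wilcoxon
signed-rank test, two-sided, α = 0.05; families of post-hoc contrasts are
Holm-adjusted; mean differences carry nonparametric bootstrap CIs
(participants resampled with replacement, N = 1000, percentile method —
nonparametric rather than parametric because no fitted hierarchical model is
assumed). Mixed-effects modelling (GLMMs with beta/binomial links) is
deliberately out of scope: it is off-the-shelf machinery whose fitted
statistics are tied to a specific real dataset, and the per-participant
paired route tests the same directional claims.

## What the simulator does and does not emulate

It reproduces the block/session structure, cue statistics, category-graded
vibrotactile difficulty, and the variance composition (sensory + motor) the
analysis assumes. It does not model learning across blocks (the task
withholds feedback precisely to prevent it), priors over the discrete target
set, biomechanics, eye movements, or sequential dependencies. Passing
recovery tests therefore certify the *pipeline* — that the estimators
recover known generating parameters — not any claim about real
participants.

## Numerical choices and problem sizes

- Degenerate inputs: circular summaries require n ≥ 2 and flag R ≈ 0 (SD
  undefined) as infinite; identical paired vectors return p = 1 flagged
  `degenerate`; constant nonzero paired differences raise.
- Hit scoring uses a 1e-9° guard on the closed arc boundary.
- Validation studies use 31 observers. Parameter-recovery runs use 100
  blocks per participant (200 bimodal trials per uncertainty cell — enough
  that the mean weight error across observers resolves 0.05) with 5 ms
  trajectory sampling; the 2 kHz hardware rate is the default for data-scale
  use, and the mid-reach interpolation makes angular features insensitive to
  the sampling rate. Strategy-dissociation runs use the standard 1152-trial
  schedule.
- At 0° visual uncertainty the default SDs (2° vs 12°) predict a variance
  reduction of ~0.1 deg², below Monte-Carlo resolution at these sizes;
  reduction tests are therefore meaningful at the 15/30/60° levels.

## Known limitations

- The fusion algebra is exact for linear variances; circular estimators
  introduce ~1% systematic deviations at 25–30° SDs, well inside the
  recovery tolerances but visible at extreme noise levels.
- The intensity-confusion mechanism is one concrete realization of
  "participants misread two-intensity cues"; real confusion structure
  (e.g. motor-swap errors) may differ.
- The scheduler balances direction × uncertainty × modality cells to within
  one trial but does not enforce exact counterbalancing across sessions.
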
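"""Named observer scenarios used throughout validation.

These bundle the study conditions under which the pipeline's claims are
checked by parameter recovery:

* ``recovery``: an MLE-optimal observer with uniform vibrotactile reliability
  (σ_VIS per uncertainty level 2/8/15/25°, σ_VIB 12°, σ_motor 3°) — empirical
  weights and bimodal SDs should recover the closed-form predictions.
* ``switching``: identical noise but a minimum-variance cue-switching
  strategy — no variance reduction below the better single cue.
* ``confusion``: intermediate-direction vibrotactile percepts are noisier
  (25°) and biased toward the nearest cardinal (15°), while the observer
  still weights cues as if vibrotactile reliability were uniform —
  overconfidence in hard-to-discriminate intensity cues. MLE predictions are
  violated on the full direction set but hold on the cardinal+oblique subset.
"""

from __future__ import annotations

from .config import ObserverParams, StudyConfig, TaskConfig

__all__ = ["recovery_observer", "switching_observer", "confusion_observer",
           "recovery_study", "SCENARIOS"]

_SIGMA_VIS = {0.0: 2.0, 15.0: 8.0, 30.0: 15.0, 60.0: 25.0}
_UNIFORM_VIB = {"cardinal": 12.0, "oblique": 12.0, "intermediate": 12.0}


def recovery_observer() -> ObserverParams:
    return ObserverParams(sigma_vis_deg=dict(_SIGMA_VIS),
                          sigma_vib_deg=dict(_UNIFORM_VIB),
                          sigma_motor_deg=3.0, strategy="mle")


def switching_observer() -> ObserverParams:
    return ObserverParams(sigma_vis_deg=dict(_SIGMA_VIS),
                          sigma_vib_deg=dict(_UNIFORM_VIB),
                          sigma_motor_deg=3.0, strategy="switch_min_variance")


def confusion_observer() -> ObserverParams:
    return ObserverParams(
        sigma_vis_deg=dict(_SIGMA_VIS),
        sigma_vib_deg={"cardinal": 12.0, "oblique": 12.0, "intermediate": 25.0},
        assumed_sigma_vib_deg=dict(_UNIFORM_VIB),
        vib_bias_deg={"cardinal": 0.0, "oblique": 0.0, "intermediate": 15.0},
        sigma_motor_deg=3.0, strategy="mle")


SCENARIOS = {
    "recovery": recovery_observer,
    "switching": switching_observer,
    "confusion": confusion_observer,
}


def recovery_study(observer: ObserverParams | None = None,
                   n_participants: int = 31,
                   blocks: int = 100,
                   sample_dt_ms: float = 5.0,
                   seed: int | None = None) -> StudyConfig:
    """A study sized for parameter recovery: with 100 blocks per participant
    each bimodal uncertainty cell holds 200 trials (400 for VIS cells).

    Trajectories are sampled at 5 ms rather than the hardware's 0.5 ms; the
    mid-reach readout interpolates linearly, so angular features are
    unaffected while simulation cost drops tenfold.
    """
    task = TaskConfig(blocks_session1=blocks // 2,
                      blocks_session2=blocks - blocks // 2,
                      sample_dt_ms=sample_dt_ms)
    return StudyConfig(task=task, n_participants=n_participants,
                       observer=observer or recovery_observer(), seed=seed)
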
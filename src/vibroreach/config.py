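"""Configuration objects for the task, the simulated observer, and a study.

Defaults reproduce the published center-out paradigm: 16 ring directions,
a 90–110 mm target ring with targets at 100 mm, four visual uncertainty
levels (0/15/30/60° bar-cloud SD, 5 bars), 32-trial blocks alternating
between visual-only and vibrotactile-containing blocks, 14 + 22 blocks over
two sessions (1152 trials), 1000 ms reaction- and movement-time limits, and
2 kHz hand-position sampling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

__all__ = ["TaskConfig", "ObserverParams", "StudyConfig", "load_config", "ConfigError"]

UNCERTAINTY_LEVELS_DEG = (0.0, 15.0, 30.0, 60.0)
CATEGORIES = ("cardinal", "oblique", "intermediate")


class ConfigError(ValueError):
    """Invalid configuration."""


@dataclass
class TaskConfig:
    """Geometry, timing and block structure of the center-out task."""

    n_directions: int = 16
    ring_inner_mm: float = 90.0
    ring_outer_mm: float = 110.0
    target_distance_mm: float = 100.0
    target_arc_mm: float = 20.0
    fixation_radius_mm: float = 10.0
    uncertainty_levels_deg: List[float] = field(default_factory=lambda: list(UNCERTAINTY_LEVELS_DEG))
    n_bars: int = 5
    block_size: int = 32
    blocks_session1: int = 14
    blocks_session2: int = 22
    max_rt_ms: float = 1000.0
    max_mt_ms: float = 1000.0
    cue_duration_ms: float = 1500.0
    hold_ms: float = 300.0
    sample_dt_ms: float = 0.5
    #: fraction of trials in vibrotactile-containing blocks that are bimodal
    bimodal_fraction: float = 0.5
    #: eccentricity at which the mid-reach angle is read out (half target distance)
    mid_reach_eccentricity_mm: Optional[float] = None
    #: eccentricity whose crossing is scored for hits (default: ring entry)
    scoring_eccentricity_mm: Optional[float] = None
    onset_speed_threshold: float = 0.02  # mm/ms
    start_radius_mm: float = 2.0
    overshoot_mm: float = 5.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_directions < 1:
            raise ConfigError("n_directions must be >= 1")
        for name in ("ring_inner_mm", "ring_outer_mm", "target_distance_mm",
                     "target_arc_mm", "max_rt_ms", "max_mt_ms", "cue_duration_ms",
                     "hold_ms", "sample_dt_ms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not self.ring_inner_mm <= self.target_distance_mm <= self.ring_outer_mm:
            raise ConfigError("target_distance_mm must lie between the ring radii")
        if any(u < 0 for u in self.uncertainty_levels_deg):
            raise ConfigError("uncertainty levels must be >= 0")
        if not 0.0 <= self.bimodal_fraction <= 1.0:
            raise ConfigError("bimodal_fraction must be in [0, 1]")
        if self.block_size < 1 or self.blocks_session1 < 0 or self.blocks_session2 < 0:
            raise ConfigError("block counts must be non-negative, block_size >= 1")

    @property
    def mid_eccentricity_mm(self) -> float:
        if self.mid_reach_eccentricity_mm is not None:
            return self.mid_reach_eccentricity_mm
        return self.target_distance_mm / 2.0

    @property
    def scoring_mm(self) -> float:
        if self.scoring_eccentricity_mm is not None:
            return self.scoring_eccentricity_mm
        return self.ring_inner_mm

    @property
    def half_arc_deg(self) -> float:
        """Half angular width of the target arc, arc length over circumference."""
        import math
        return math.degrees(self.target_arc_mm / (2.0 * self.target_distance_mm))

    @property
    def n_blocks(self) -> int:
        return self.blocks_session1 + self.blocks_session2

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.block_size

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        return cls(**d)


def _uniform_map(keys, value) -> Dict:
    return {k: float(value) for k in keys}


@dataclass
class ObserverParams:
    """A simulated multisensory observer performing the reach task.

    ``sigma_vis_deg`` maps each visual uncertainty level to the angular SD of
    the visual unimodal estimate; at 0° uncertainty the target is revealed, so
    a small nonzero floor (default 2°) stands in for residual perceptual
    noise. ``sigma_vib_deg`` maps direction category to the vibrotactile SD:
    the defaults grade cardinal < oblique < intermediate, emulating the
    observed difficulty of discriminating two simultaneous motor intensities;
    they are free simulator parameters, not measured values.

    ``assumed_sigma_vib_deg`` / ``assumed_sigma_vis_deg``, when set, are the
    reliabilities the observer *believes* and uses for weighting, while the
    ``sigma_*`` values generate the actual noise — a mismatch models
    overconfident weighting of hard-to-interpret cues. ``vib_bias_deg`` adds a
    deterministic bias of intermediate-direction vibrotactile percepts toward
    the nearest cardinal (intensity-confusion bias).

    ``strategy`` selects the integration rule on bimodal trials: ``mle``
    (variance-weighted average), ``fixed_weight`` (constant visual weight
    ``strategy_weight``), ``switch_min_variance`` (use only the cue believed
    more reliable), or ``switch_probabilistic`` (visual cue with probability
    ``strategy_p``, else vibrotactile).
    """

    sigma_vis_deg: Dict[float, float] = field(
        default_factory=lambda: {0.0: 2.0, 15.0: 8.0, 30.0: 15.0, 60.0: 25.0})
    sigma_vib_deg: Dict[str, float] = field(
        default_factory=lambda: {"cardinal": 8.0, "oblique": 12.0, "intermediate": 18.0})
    sigma_motor_deg: float = 3.0
    strategy: str = "mle"
    strategy_weight: float = 0.5   # fixed_weight: visual weight w
    strategy_p: float = 0.5        # switch_probabilistic: P(use visual)
    assumed_sigma_vis_deg: Optional[Dict[float, float]] = None
    assumed_sigma_vib_deg: Optional[Dict[str, float]] = None
    vib_bias_deg: Dict[str, float] = field(
        default_factory=lambda: {"cardinal": 0.0, "oblique": 0.0, "intermediate": 0.0})
    rt_loc_ms: float = 300.0
    rt_scale_ms: float = 40.0
    mt_loc_ms: float = 500.0
    mt_scale_ms: float = 60.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        self.sigma_vis_deg = {float(k): float(v) for k, v in self.sigma_vis_deg.items()}
        self.sigma_vib_deg = {str(k): float(v) for k, v in self.sigma_vib_deg.items()}
        if self.assumed_sigma_vis_deg is not None:
            self.assumed_sigma_vis_deg = {float(k): float(v)
                                          for k, v in self.assumed_sigma_vis_deg.items()}
        if self.assumed_sigma_vib_deg is not None:
            self.assumed_sigma_vib_deg = {str(k): float(v)
                                          for k, v in self.assumed_sigma_vib_deg.items()}
        self.validate()

    def validate(self) -> None:
        if any(v < 0 for v in self.sigma_vis_deg.values()):
            raise ConfigError("visual SDs must be >= 0")
        levels = sorted(self.sigma_vis_deg)
        sds = [self.sigma_vis_deg[u] for u in levels]
        if any(b < a for a, b in zip(sds, sds[1:])):
            raise ConfigError("sigma_vis_deg must be non-decreasing in uncertainty level")
        if any(v < 0 for v in self.sigma_vib_deg.values()):
            raise ConfigError("vibrotactile SDs must be >= 0")
        if self.sigma_motor_deg < 0:
            raise ConfigError("sigma_motor_deg must be >= 0")
        if self.strategy not in ("mle", "fixed_weight", "switch_min_variance",
                                 "switch_probabilistic"):
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        for name in ("strategy_weight", "strategy_p", "lapse_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")

    def believed_sigma_vis(self, uncertainty: float) -> float:
        m = self.assumed_sigma_vis_deg or self.sigma_vis_deg
        return m[float(uncertainty)]

    def believed_sigma_vib(self, category: str) -> float:
        m = self.assumed_sigma_vib_deg or self.sigma_vib_deg
        return m[category]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverParams":
        return cls(**d)


@dataclass
class StudyConfig:
    """A full synthetic study: task, cohort size, observers, seed."""

    task: TaskConfig = field(default_factory=TaskConfig)
    n_participants: int = 31
    observer: ObserverParams = field(default_factory=ObserverParams)
    #: optional per-participant overrides; entry i updates participant i's observer
    observer_overrides: Optional[List[dict]] = None
    seed: Optional[int] = None

    def observers(self) -> List[ObserverParams]:
        base = self.observer.to_dict()
        out = []
        for i in range(self.n_participants):
            d = dict(base)
            if self.observer_overrides and i < len(self.observer_overrides):
                d.update(self.observer_overrides[i])
            out.append(ObserverParams.from_dict(d))
        return out

    def to_dict(self) -> dict:
        return {
            "task": self.task.to_dict(),
            "n_participants": self.n_participants,
            "observer": self.observer.to_dict(),
            "observer_overrides": self.observer_overrides,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        task = TaskConfig.from_dict(d.get("task", {}))
        observer = ObserverParams.from_dict(d.get("observer", {}))
        return cls(
            task=task,
            n_participants=int(d.get("n_participants", 31)),
            observer=observer,
            observer_overrides=d.get("observer_overrides"),
            seed=d.get("seed"),
        )


def load_config(path: str | Path) -> StudyConfig:
    """Load a study configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return StudyConfig.from_dict(data)
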
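"""Deterministic codec between target directions and 4-motor vibration patterns.

Four eccentric-rotating-mass (ERM) motors on the reaching arm each encode one
cardinal direction. The pattern slots are indexed by encoded cardinal
(0°, 90°, 180°, 270°); where a motor physically sits on the arm is metadata
and plays no computational role.

Encoding rules for the 16 ring directions (multiples of 22.5°):

* cardinal (multiple of 90°): the one matching motor at full intensity;
* oblique (odd multiple of 45°): both flanking motors at full intensity;
* intermediate (remaining multiples of 22.5°): the motor of the nearest
  cardinal at full intensity, the other flanking motor at low intensity.

``FULL`` and ``LOW`` are dimensionless drive intensities. The default low/full
ratio 0.4/1.1 mirrors the approximate peak accelerations of the two drive
levels of the ERM motors (~1.1 g fully driven, ~0.4 g at the reduced level);
it is configurable because only the ordering, not the perceptual scale, is
defined by the hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

__all__ = [
    "FULL",
    "LOW",
    "CARDINALS_DEG",
    "MotorPattern",
    "InvalidDirectionError",
    "InvalidPatternError",
    "direction_category",
    "encode_direction",
    "decode_direction",
    "all_directions",
]

FULL: float = 1.0
LOW: float = 0.4 / 1.1  # ~0.364, ratio of the two approximate drive amplitudes

#: Cardinal direction encoded by each pattern slot.
CARDINALS_DEG: Tuple[float, float, float, float] = (0.0, 90.0, 180.0, 270.0)


class InvalidDirectionError(ValueError):
    """Raised for target directions that are not multiples of 22.5° in [0, 360)."""


class InvalidPatternError(ValueError):
    """Raised for motor patterns that violate the codec invariants."""


@dataclass(frozen=True)
class MotorPattern:
    """Activation intensities of the four motors, slot i encoding CARDINALS_DEG[i].

    Invariants: exactly 1 or 2 nonzero entries; at least one entry equals
    ``full``; two active motors encode adjacent cardinals (90° apart), never
    opposed ones.
    """

    intensities: Tuple[float, float, float, float]
    full: float = FULL
    low: float = LOW

    def __post_init__(self) -> None:
        if len(self.intensities) != 4:
            raise InvalidPatternError("pattern must have 4 intensity slots")
        object.__setattr__(self, "intensities", tuple(float(v) for v in self.intensities))
        self.validate()

    def validate(self) -> None:
        active = [i for i, v in enumerate(self.intensities) if v != 0.0]
        if len(active) not in (1, 2):
            raise InvalidPatternError(
                f"pattern must activate 1 or 2 motors, got {len(active)}"
            )
        if not any(v == self.full for v in self.intensities):
            raise InvalidPatternError("at least one motor must be fully active")
        allowed = {0.0, self.full, self.low}
        if any(v not in allowed for v in self.intensities):
            raise InvalidPatternError(
                f"intensities must be in {{0, LOW={self.low}, FULL={self.full}}}"
            )
        if len(active) == 2 and (active[1] - active[0]) % 2 == 0:
            raise InvalidPatternError("two active motors must encode adjacent cardinals")

    def serialize(self) -> str:
        """4 comma-separated floats, the trial-table representation."""
        return ",".join(format(v, ".17g") for v in self.intensities)

    @classmethod
    def deserialize(cls, text: str, full: float = FULL, low: float = LOW) -> "MotorPattern":
        parts = [float(p) for p in text.split(",")]
        return cls(tuple(parts), full=full, low=low)  # type: ignore[arg-type]


def _check_direction(target_deg: float) -> float:
    d = float(target_deg) % 360.0
    if (d / 22.5) != round(d / 22.5):
        raise InvalidDirectionError(
            f"target direction must be a multiple of 22.5°, got {target_deg}"
        )
    return d


def direction_category(target_deg: float) -> str:
    """Classify a ring direction as 'cardinal', 'oblique' or 'intermediate'."""
    d = _check_direction(target_deg)
    if d % 90.0 == 0.0:
        return "cardinal"
    if d % 45.0 == 0.0:
        return "oblique"
    return "intermediate"


def encode_direction(target_deg: float, full: float = FULL, low: float = LOW) -> MotorPattern:
    """Map a ring direction (multiple of 22.5°) to its motor pattern."""
    d = _check_direction(target_deg)
    intensities = [0.0, 0.0, 0.0, 0.0]
    cat = direction_category(d)
    if cat == "cardinal":
        intensities[int(d // 90.0)] = full
    elif cat == "oblique":
        lower = int(d // 90.0)  # cardinal just below, e.g. 45° -> motors 0° and 90°
        intensities[lower] = full
        intensities[(lower + 1) % 4] = full
    else:  # intermediate: nearest cardinal full, other flank low
        lower = int(d // 90.0)
        upper = (lower + 1) % 4
        if d % 90.0 == 22.5:
            intensities[lower] = full
            intensities[upper] = low
        else:  # offset 67.5, nearest cardinal is the upper one
            intensities[upper] = full
            intensities[lower] = low
    return MotorPattern(tuple(intensities), full=full, low=low)  # type: ignore[arg-type]


def decode_direction(pattern: MotorPattern) -> float:
    """Inverse of :func:`encode_direction`; raises on invariant-violating patterns."""
    pattern.validate()
    ints = pattern.intensities
    active = [i for i, v in enumerate(ints) if v != 0.0]
    if len(active) == 1:
        return CARDINALS_DEG[active[0]]
    i, j = active
    # order the pair so that j is 90° counter-clockwise of i (handles the 270/0 wrap)
    if (j - i) % 4 != 1:
        i, j = j, i
    base = CARDINALS_DEG[i]
    vi, vj = ints[i], ints[j]
    if vi == pattern.full and vj == pattern.full:
        return (base + 45.0) % 360.0
    if vi == pattern.full:
        return (base + 22.5) % 360.0
    return (base + 67.5) % 360.0


def all_directions(n: int = 16) -> list[float]:
    """The ring directions, multiples of 360/n degrees (default the 16 of the task)."""
    step = 360.0 / n
    return [i * step for i in range(n)]
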
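"""Angle arithmetic and the von Mises concentration <-> circular-SD mapping.

Convention throughout the package: angles in degrees, 0° rightward,
counter-clockwise positive. Absolute angles live in [0, 360); signed
deviations live in (-180, 180].
"""

from __future__ import annotations

import functools
import math

import numpy as np
from scipy import optimize, special

__all__ = [
    "wrap_deg",
    "wrap_signed_deg",
    "ang_diff_deg",
    "abs_ang_diff_deg",
    "kappa_from_circular_sd_deg",
    "circular_sd_deg_from_kappa",
]


def wrap_deg(angle_deg):
    """Wrap angle(s) to [0, 360)."""
    return np.asarray(angle_deg, dtype=float) % 360.0


def wrap_signed_deg(angle_deg):
    """Wrap angle(s) to (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    return -((180.0 - a) % 360.0 - 180.0)


def ang_diff_deg(a_deg, b_deg):
    """Signed angular difference a - b in (-180, 180]."""
    return wrap_signed_deg(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def abs_ang_diff_deg(a_deg, b_deg):
    """Absolute angular difference in [0, 180]."""
    return np.abs(ang_diff_deg(a_deg, b_deg))


def _mean_resultant_length(kappa: float) -> float:
    # I1(k)/I0(k), computed with exponentially scaled Bessel functions for stability
    return float(special.i1e(kappa) / special.i0e(kappa))


@functools.lru_cache(maxsize=256)
def kappa_from_circular_sd_deg(sd_deg: float) -> float:
    """Concentration kappa of a von Mises whose circular SD equals ``sd_deg``.

    Circular SD is defined as sqrt(-2 ln R) with R = I1(kappa)/I0(kappa).
    ``sd_deg == 0`` returns ``inf`` (degenerate point mass). Well conditioned
    for SDs up to well beyond the 60° used in practice.
    """
    if sd_deg < 0:
        raise ValueError(f"circular SD must be >= 0, got {sd_deg}")
    if sd_deg == 0:
        return math.inf
    sd_rad = math.radians(float(sd_deg))
    r_target = math.exp(-0.5 * sd_rad * sd_rad)
    if r_target >= 1.0 - 1e-15:
        return math.inf
    return float(
        optimize.brentq(lambda k: _mean_resultant_length(k) - r_target, 1e-9, 1e9, xtol=1e-12)
    )


def circular_sd_deg_from_kappa(kappa: float) -> float:
    """Inverse of :func:`kappa_from_circular_sd_deg`."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if math.isinf(kappa):
        return 0.0
    r = _mean_resultant_length(kappa)
    return math.degrees(math.sqrt(-2.0 * math.log(r)))
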
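"""Circular statistics for angle samples.

For a sample of angles :math:`\\theta_j` (degrees), the circular mean is

.. math:: \\bar\\theta = \\mathrm{atan2}\\Big(\\tfrac1n\\sum_j \\sin\\theta_j,\\;
          \\tfrac1n\\sum_j \\cos\\theta_j\\Big),

the resultant vector length is the modulus of that mean unit vector,

.. math:: R_v = \\Big|\\tfrac1n\\sum_j (\\sin\\theta_j, \\cos\\theta_j)\\Big| \\in [0,1],

and the circular standard deviation is :math:`S = \\sqrt{-2\\ln R_v}`
(radians; reported here in degrees).  :math:`R_v = 1` means all angles
coincide; :math:`R_v = 0` means the sample is balanced and the mean
direction is undefined — that case raises
:class:`~polywhorl.errors.UndefinedStatisticError` rather than returning an
arbitrary angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import UndefinedStatisticError

__all__ = [
    "circ_mean",
    "resultant_length",
    "circ_sd",
    "angle_stats",
    "circular_median",
    "AngleStats",
]

#: below this resultant length the mean direction is treated as undefined
RESULTANT_EPS = 1e-12


def _mean_vector(angles: Sequence[float]) -> tuple[float, float]:
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle sample")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite angle in sample")
    rad = np.deg2rad(a)
    return float(np.mean(np.sin(rad))), float(np.mean(np.cos(rad)))


def resultant_length(angles: Sequence[float]) -> float:
    """Resultant vector length ``R_v`` in [0, 1]."""
    s, c = _mean_vector(angles)
    return min(float(np.hypot(s, c)), 1.0)


def circ_mean(angles: Sequence[float]) -> float:
    """Circular mean direction in degrees in [0, 360)."""
    s, c = _mean_vector(angles)
    if np.hypot(s, c) < RESULTANT_EPS:
        raise UndefinedStatisticError(
            "circular mean undefined: resultant vector length is 0"
        )
    out = float(np.rad2deg(np.arctan2(s, c))) % 360.0
    return 0.0 if out >= 360.0 else out


def circ_sd(angles: Sequence[float]) -> float:
    """Circular standard deviation ``sqrt(-2 ln R_v)`` in degrees."""
    r = resultant_length(angles)
    if r < RESULTANT_EPS:
        raise UndefinedStatisticError(
            "circular SD undefined (infinite): resultant vector length is 0"
        )
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))))


@dataclass(frozen=True)
class AngleStats:
    """Summary of an angle sample: mean direction (None when undefined),
    resultant length, circular SD in degrees (inf when undefined), n."""

    mean: Optional[float]
    resultant: float
    circ_sd: float
    n: int

    @property
    def defined(self) -> bool:
        return self.mean is not None


def angle_stats(angles: Sequence[float]) -> AngleStats:
    """Compute all three circular statistics, flagging the undefined case
    instead of raising."""
    r = resultant_length(angles)
    n = len(angles)
    if r < RESULTANT_EPS:
        return AngleStats(mean=None, resultant=r, circ_sd=float("inf"), n=n)
    return AngleStats(
        mean=circ_mean(angles), resultant=r, circ_sd=circ_sd(angles), n=n
    )


def circular_median(angles: Sequence[float], period: float = 360.0) -> float:
    """Circular median on a circle of the given period (degrees).

    The median is the sample point minimising the summed circular distance
    to all other points; ties go to the smallest angle.  Used for
    alternation offsets, where robustness to a single jittered tentacle
    matters more than efficiency.
    """
    a = np.asarray(angles, dtype=float) % period
    if a.size == 0:
        raise ValueError("empty angle sample")
    diff = np.abs(a[:, None] - a[None, :])
    circ = np.minimum(diff, period - diff)
    cost = circ.sum(axis=1)
    winners = np.flatnonzero(cost == cost.min())
    return float(np.min(a[winners]))
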
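"""Population-level symmetry typing and size-symmetry correlation.

The primary-ring tentacle count types each polyp as tri- (3), tetra- (4)
or pentaradial (5); other counts are "other".  Population proportions are
reported as percentages truncated (not rounded) to two decimals, which is
how 12/73 prints as 16.43.  The size analysis correlates the symmetry
type, encoded ordinally as its tentacle count {3,4,5}, against polyp
diameter and against the mean 3D distance between adjacent tentacles of
the primary ring, using the Pearson product-moment formula

.. math:: r = \\frac{n\\Sigma xy - \\Sigma x\\,\\Sigma y}
          {\\sqrt{(n\\Sigma x^2-(\\Sigma x)^2)(n\\Sigma y^2-(\\Sigma y)^2)}}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import PolypArrangement
from .errors import UndefinedStatisticError
from .periodicity import NOT_SIGNIFICANT, PeriodCall

__all__ = [
    "SymmetryCall",
    "CorrelationResult",
    "symmetry_of_count",
    "tally_symmetries",
    "pearson_r",
    "adjacent_distances_3d",
    "size_symmetry_analysis",
    "truncate_percent",
]

_SYMMETRY_NAMES = {3: "tri", 4: "tetra", 5: "penta"}


def symmetry_of_count(primary_count: int) -> str:
    return _SYMMETRY_NAMES.get(primary_count, "other")


@dataclass(frozen=True)
class SymmetryCall:
    """Symmetry type of one polyp, from its primary-ring count."""

    polyp_id: str
    primary_count: int
    period_call: PeriodCall = NOT_SIGNIFICANT

    @property
    def symmetry(self) -> str:
        return symmetry_of_count(self.primary_count)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    x_label: str = "x"
    y_label: str = "y"


def truncate_percent(fraction: float) -> float:
    """Percentage truncated to two decimals (41/73 -> 56.16, 12/73 -> 16.43)."""
    return math.floor(fraction * 10000.0) / 100.0


def tally_symmetries(calls: Sequence[SymmetryCall]) -> pd.DataFrame:
    """Counts and truncated percentages per primary-ring count class.

    Returns a DataFrame with columns ``primary_count``, ``symmetry``,
    ``count``, ``percent`` sorted by class; percentages are out of all
    classified polyps.
    """
    if not calls:
        raise ValueError("no symmetry calls to tally")
    total = len(calls)
    counts: Dict[int, int] = {}
    for c in calls:
        counts[c.primary_count] = counts.get(c.primary_count, 0) + 1
    rows = [
        {
            "primary_count": k,
            "symmetry": symmetry_of_count(k),
            "count": v,
            "percent": truncate_percent(v / total),
        }
        for k, v in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def pearson_r(x: Sequence[float], y: Sequence[float],
              x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    """Pearson product-moment correlation by the summation formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    den_x = n * sxx - sx * sx
    den_y = n * syy - sy * sy
    if den_x <= 0 or den_y <= 0:
        raise UndefinedStatisticError(
            f"correlation undefined: zero variance in {'x' if den_x <= 0 else 'y'}"
        )
    r = (n * sxy - sx * sy) / math.sqrt(den_x * den_y)
    return CorrelationResult(r=float(np.clip(r, -1.0, 1.0)), n=n,
                             x_label=x_label, y_label=y_label)


def adjacent_distances_3d(arr: PolypArrangement, ring: Sequence[int]) -> List[float]:
    """3D Euclidean distances between angularly adjacent tentacle bases of
    one ring (circular adjacency, so length = ring size)."""
    if len(ring) < 2:
        raise ValueError("ring must contain at least 2 tentacles")
    missing = [arr.tentacles[i].index for i in ring if arr.tentacles[i].xyz is None]
    if missing:
        raise ValueError(
            f"polyp {arr.polyp_id!r}: missing xyz for tentacle index(es) {missing}"
        )
    order = sorted(ring, key=lambda i: arr.tentacles[i].theta)
    pts = np.array([arr.tentacles[i].xyz for i in order], dtype=float)
    nxt = np.roll(pts, -1, axis=0)
    return [float(d) for d in np.linalg.norm(nxt - pts, axis=1)]


def size_symmetry_analysis(
    calls: Sequence[SymmetryCall],
    diameters: Sequence[Optional[float]],
    mean_adjacent_distances: Sequence[Optional[float]],
) -> Dict[str, CorrelationResult]:
    """Correlate symmetry type (as {3,4,5}) with polyp diameter and with the
    mean adjacent-tentacle distance in the primary ring.

    Polyps whose primary count is not in {3,4,5} or that lack the relevant
    measurement are excluded from each analysis.  Raises on n < 3.
    """
    if not (len(calls) == len(diameters) == len(mean_adjacent_distances)):
        raise ValueError("calls, diameters and distances must align")
    xs_d, ys_d, xs_t, ys_t = [], [], [], []
    for call, diam, dist in zip(calls, diameters, mean_adjacent_distances):
        if call.primary_count not in (3, 4, 5):
            continue
        if diam is not None:
            xs_d.append(call.primary_count)
            ys_d.append(diam)
        if dist is not None:
            xs_t.append(call.primary_count)
            ys_t.append(dist)
    if len(xs_d) < 3 or len(xs_t) < 3:
        raise ValueError(
            f"need >= 3 classified polyps with measurements "
            f"(got {len(xs_d)} diameters, {len(xs_t)} distances)"
        )
    return {
        "diameter": pearson_r(xs_d, ys_d, "symmetry_type", "diameter"),
        "adjacent_distance": pearson_r(
            xs_t, ys_t, "symmetry_type", "mean_adjacent_distance"
        ),
    }
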
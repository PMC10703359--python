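"""Per-polyp arrangement metrics.

The whorl/spiral dichotomy rests on two series derived from the mouth
ordering of tentacles: internode lengths ``dh_i = h_{i+1} - h_i`` and
successive-organ angles ``phi_i = (theta_{i+1} - theta_i) mod 360``.  In a
whorled arrangement internodes are near zero within a ring with a large
gap between rings; in a spiral both series are non-zero and constant.

A *ring-defining gap* is an internode strictly greater than twice the mean
of all internodes of the polyp, ``sum(h_{i+1}-h_i)/(m-1)``.  Rings are the
runs of tentacles between gaps; the most oral ring is the *primary ring*
and its tentacle count defines the radial symmetry type (3 = tri,
4 = tetra, 5 = penta).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .circular import AngleStats, angle_stats, circular_median
from .datamodel import PolypArrangement

__all__ = [
    "InternodeSeries",
    "RingPartition",
    "SuccessiveAngles",
    "AlternationOffset",
    "internode_lengths",
    "successive_angles",
    "detect_rings",
    "nearest_angles_within_ring",
    "primary_ring_stats",
    "alternation_offsets",
    "GAP_MULTIPLIER",
]

#: a gap is called where dh > GAP_MULTIPLIER * mean internode
GAP_MULTIPLIER = 2.0


@dataclass(frozen=True)
class InternodeSeries:
    """Internode lengths ``dh_i``, length m-1, plus their mean."""

    values: Tuple[float, ...]

    @property
    def mean_internode(self) -> float:
        return float(np.mean(self.values))


@dataclass
class RingPartition:
    """Contiguous grouping of tentacle positions (0-based, mouth order)
    into rings, oral to aboral.

    ``gap_positions`` holds the 1-based internode index ``i`` of every
    called gap (the gap lies between tentacles ``i`` and ``i+1``).  When no
    gap is called the partition is a single ring and ``no_gap`` is True —
    such polyps are non-whorled and are excluded from symmetry typing.
    """

    rings: List[Tuple[int, ...]]
    gap_positions: Tuple[int, ...] = ()
    no_gap: bool = False

    @property
    def primary_ring(self) -> Tuple[int, ...]:
        return self.rings[0]

    @property
    def primary_count(self) -> int:
        return len(self.rings[0])


@dataclass(frozen=True)
class SuccessiveAngles:
    """Successive-organ angles ``phi_i`` in [0, 360), length m-1."""

    values: Tuple[float, ...]


@dataclass(frozen=True)
class AlternationOffset:
    """Circular offset of one ring relative to the previous, modulo the
    period angle 360/ring-size.  Ideal alternation gives half the period.
    ``unequal_sizes`` flags ring pairs of different size, where the offset
    was computed on the smaller ring's period."""

    value_deg: float
    period_deg: float
    unequal_sizes: bool = False


def internode_lengths(arr: PolypArrangement) -> InternodeSeries:
    """Axial distances of successive tentacles in mouth order (length m-1)."""
    if arr.m < 2:
        raise ValueError(f"polyp {arr.polyp_id!r}: need >= 2 tentacles for internodes")
    return InternodeSeries(values=tuple(np.diff(arr.h)))


def successive_angles(arr: PolypArrangement) -> SuccessiveAngles:
    """Angular differences of successive tentacles in mouth order."""
    if arr.m < 2:
        raise ValueError(f"polyp {arr.polyp_id!r}: need >= 2 tentacles")
    phi = np.diff(arr.theta) % 360.0
    return SuccessiveAngles(values=tuple(phi))


def detect_rings(series: InternodeSeries, gap_multiplier: float = GAP_MULTIPLIER) -> RingPartition:
    """Partition tentacles into rings by the gap rule.

    A gap is called at internode ``i`` (1-based) iff
    ``dh_i > gap_multiplier * mean(dh)``.  With all internodes equal (a
    single level, or a perfect spiral) no gap exists and the single-ring
    partition is flagged ``no_gap``.
    """
    dh = np.asarray(series.values, dtype=float)
    m = dh.size + 1
    mean = dh.mean()
    gaps = [i + 1 for i in range(dh.size) if dh[i] > gap_multiplier * mean and mean > 0]
    if not gaps:
        return RingPartition(rings=[tuple(range(m))], gap_positions=(), no_gap=True)
    rings = []
    start = 0
    for g in gaps:
        rings.append(tuple(range(start, g)))
        start = g
    rings.append(tuple(range(start, m)))
    return RingPartition(rings=rings, gap_positions=tuple(gaps), no_gap=False)


def nearest_angles_within_ring(
    arr: PolypArrangement, ring: Sequence[int]
) -> List[float]:
    """Circular gaps between angularly adjacent tentacles of one ring.

    Members are sorted by position angle; the returned gaps (length = ring
    size) sum to 360 degrees.
    """
    if len(ring) < 2:
        raise ValueError("ring must contain at least 2 tentacles")
    theta = np.sort(arr.theta[list(ring)])
    gaps = np.diff(np.concatenate([theta, [theta[0] + 360.0]]))
    return [float(g) for g in gaps]


def primary_ring_stats(
    arr: PolypArrangement, partition: RingPartition | None = None
) -> Tuple[AngleStats, int]:
    """Circular statistics of nearest-tentacle angles in the primary ring,
    plus the ring's tentacle count."""
    if partition is None:
        partition = detect_rings(internode_lengths(arr))
    ring = partition.primary_ring
    gaps = nearest_angles_within_ring(arr, ring)
    return angle_stats(gaps), len(ring)


def alternation_offsets(
    arr: PolypArrangement, partition: RingPartition
) -> List[AlternationOffset]:
    """Angular offset of each ring relative to the ring above it.

    For each successive ring pair the offset is the circular median of all
    pairwise angle differences ``theta(lower) - theta(upper)`` taken modulo
    the period angle 360/ring-size.  Ideal alternation (half-period shift,
    as in alternate whorled phyllotaxis) yields period/2.
    """
    if len(partition.rings) < 2:
        raise ValueError("need at least 2 rings for alternation offsets")
    out = []
    theta = arr.theta
    for upper, lower in zip(partition.rings, partition.rings[1:]):
        size = max(len(upper), len(lower))
        if size < 1:
            continue
        period = 360.0 / size
        offs = [
            (theta[j] - theta[i]) % period for i in upper for j in lower
        ]
        out.append(
            AlternationOffset(
                value_deg=circular_median(offs, period=period),
                period_deg=period,
                unequal_sizes=(len(upper) != len(lower)),
            )
        )
    return out
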
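"""Seeded generators for synthetic arrangements and populations.

These generators carry the statistical structure the analysis assumes —
whorls (rings of ``per_ring`` tentacles at shared axial levels separated
by large internode gaps, regular 360/per_ring intra-ring angles with
angular jitter, optional half-period alternation between successive
rings), spirals (constant rise and divergence angle), and a polymorphic
population whose primary-ring count correlates positively with body
diameter — so every analysis stage is testable without measured polyps.

Angular jitter is wrapped-Gaussian; axial jitter is truncated at
±ring_spacing/4 so rings never interleave and the generating partition
stays well defined.  Identical spec + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .datamodel import PolypArrangement, TentacleRecord

__all__ = [
    "WhorlSpec",
    "PopulationSpec",
    "gen_whorled",
    "gen_spiral",
    "gen_population",
    "PAPER_CLASS_COUNTS",
]

#: primary-ring class frequencies of the observed 73-polyp population
PAPER_CLASS_COUNTS: Dict[int, int] = {3: 13, 4: 41, 5: 12, 6: 4, 9: 2, 10: 1}


@dataclass(frozen=True)
class WhorlSpec:
    """Ideal-whorl generator settings (lengths in the unit of ``h``)."""

    n_rings: int = 5
    per_ring: int = 4
    ring_spacing: float = 50.0
    intra_ring_spread: float = 3.0
    angle_jitter: float = 8.0
    alternate: bool = True
    diameter: Optional[float] = 270.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")
        if self.per_ring < 2:
            raise ValueError("per_ring must be >= 2")
        if self.ring_spacing <= 0:
            raise ValueError("ring_spacing must be > 0")


@dataclass(frozen=True)
class PopulationSpec:
    """Polymorphic-population generator settings.

    ``class_weights`` are drawn over primary-ring counts; ``diameter_means``
    must increase over classes 3, 4, 5 so that symmetry type and diameter
    correlate positively, as in the observed polyps.
    """

    n_polyps: int = 73
    class_weights: Dict[int, float] = field(
        default_factory=lambda: {
            k: v / sum(PAPER_CLASS_COUNTS.values()) for k, v in PAPER_CLASS_COUNTS.items()
        }
    )
    diameter_means: Dict[int, float] = field(
        default_factory=lambda: {k: 30.0 + 60.0 * k for k in (3, 4, 5, 6, 9, 10)}
    )
    diameter_sd: float = 20.0
    tentacle_total_range: Tuple[int, int] = (20, 28)
    ring_spacing: float = 50.0
    intra_ring_spread: float = 3.0
    angle_jitter: float = 8.0
    #: allocate class counts deterministically (largest remainder) instead
    #: of sampling, so observed frequencies reproduce the weights exactly
    exact_proportions: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.class_weights:
            raise ValueError("class_weights must be non-empty")
        total = sum(self.class_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class_weights must sum to 1, got {total}")
        means = [self.diameter_means.get(k) for k in (3, 4, 5) if k in self.class_weights]
        means = [m for m in means if m is not None]
        if any(m2 <= m1 for m1, m2 in zip(means, means[1:])):
            raise ValueError("diameter means must strictly increase over classes 3,4,5")


def _cylinder_xyz(theta_deg: float, h: float, diameter: Optional[float]):
    if diameter is None:
        return None
    r = diameter / 2.0
    rad = np.deg2rad(theta_deg)
    return (r * np.cos(rad), r * np.sin(rad), float(h))


def gen_whorled(spec: WhorlSpec, polyp_id: str = "whorl",
                rng: Optional[np.random.Generator] = None) -> PolypArrangement:
    """Generate a whorled arrangement.

    Ring ``r`` sits at axial level ``r * ring_spacing`` plus truncated
    Gaussian jitter; tentacle ``j`` of ring ``r`` sits at angle
    ``360 j / per_ring`` plus ``r * 180 / per_ring`` when alternating, plus
    wrapped-Gaussian jitter.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    trunc = spec.ring_spacing / 4.0
    records = []
    idx = 1
    for r in range(spec.n_rings):
        base_h = r * spec.ring_spacing
        offset = (r * 180.0 / spec.per_ring) if spec.alternate else 0.0
        for j in range(spec.per_ring):
            dh = np.clip(rng.normal(0.0, spec.intra_ring_spread), -trunc, trunc) \
                if spec.intra_ring_spread > 0 else 0.0
            theta = (360.0 * j / spec.per_ring + offset
                     + (rng.normal(0.0, spec.angle_jitter) if spec.angle_jitter > 0 else 0.0)
                     ) % 360.0
            h = max(0.0, base_h + dh)
            records.append(
                TentacleRecord(index=idx, h=h, theta=theta,
                               xyz=_cylinder_xyz(theta, h, spec.diameter))
            )
            idx += 1
    return PolypArrangement(polyp_id=polyp_id, tentacles=records,
                            diameter=spec.diameter, unit="um")


def gen_spiral(divergence: float, rise: float, n: int, seed: int = 0,
               polyp_id: str = "spiral",
               diameter: Optional[float] = None) -> PolypArrangement:
    """Ideal spiral: ``h_i = i * rise``, ``theta_i = i * divergence mod 360``."""
    if n < 2:
        raise ValueError("need n >= 2 organs")
    if rise <= 0:
        raise ValueError("rise must be > 0")
    records = []
    for i in range(n):
        theta = (i * divergence) % 360.0
        h = i * rise
        records.append(
            TentacleRecord(index=i + 1, h=h, theta=theta,
                           xyz=_cylinder_xyz(theta, h, diameter))
        )
    return PolypArrangement(polyp_id=polyp_id, tentacles=records,
                            diameter=diameter, unit="um")


def gen_population(spec: PopulationSpec) -> List[PolypArrangement]:
    """Draw a polymorphic population of whorled polyps.

    Each polyp's class (primary-ring count) comes from ``class_weights``;
    its tentacle total from ``tentacle_total_range``; its diameter from the
    class mean plus Gaussian noise (floored at 10% of the mean so the
    diameter stays positive)."""
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.class_weights)
    weights = np.array([spec.class_weights[k] for k in classes], dtype=float)
    if spec.exact_proportions:
        raw = weights * spec.n_polyps
        counts = np.floor(raw).astype(int)
        remainder = spec.n_polyps - counts.sum()
        for j in np.argsort(-(raw - counts))[:remainder]:
            counts[j] += 1
        assigned = np.repeat(classes, counts)
        rng.shuffle(assigned)
    else:
        assigned = None
    lo, hi = spec.tentacle_total_range
    polyps = []
    for i in range(spec.n_polyps):
        cls = int(assigned[i]) if assigned is not None else int(rng.choice(classes, p=weights))
        total = int(rng.integers(lo, hi + 1))
        n_rings = max(2, round(total / cls))
        mean_d = spec.diameter_means.get(cls, 30.0 + 60.0 * cls)
        diameter = max(0.1 * mean_d, rng.normal(mean_d, spec.diameter_sd))
        wspec = WhorlSpec(
            n_rings=n_rings, per_ring=cls,
            ring_spacing=spec.ring_spacing,
            intra_ring_spread=spec.intra_ring_spread,
            angle_jitter=spec.angle_jitter,
            alternate=True, diameter=diameter, seed=0,
        )
        polyps.append(gen_whorled(wspec, polyp_id=f"poly{i:04d}", rng=rng))
    return polyps
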
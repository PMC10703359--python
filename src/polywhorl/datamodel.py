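"""Core domain types.

A *polyp arrangement* is the measurement substrate of the whole package:
one record per tentacle, holding the axial distance ``h`` from the mouth
along the oral-aboral axis and the position angle ``theta`` around the
body axis.  Tentacles are kept sorted by ``(h, theta)`` — "mouth order" —
because every downstream quantity (internode lengths, successive-organ
angles, ring partitions) is defined on that ordering.

Angles are stored in degrees in ``[0, 360)``; all trigonometry happens in
radians inside :mod:`polywhorl.circular`.  Lengths carry whatever unit the
data came in (micrometres for measurements, lattice cells for simulator
output); the unit travels as a metadata string and is never converted
implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import IntegrityError

__all__ = [
    "TentacleRecord",
    "PolypArrangement",
    "SimSnapshot",
    "normalize_angle",
]


def normalize_angle(theta: float) -> float:
    """Map an angle in degrees onto ``[0, 360)``.

    Raises :class:`ValueError` for non-finite input — a NaN angle must not
    silently propagate into circular statistics.
    """
    if not np.isfinite(theta):
        raise ValueError(f"non-finite angle: {theta!r}")
    out = float(theta) % 360.0
    # -1e-9 % 360 == 360.0 - 1e-9 in floats can round to 360.0 exactly
    return 0.0 if out >= 360.0 else out


@dataclass(frozen=True)
class TentacleRecord:
    """A single tentacle: rank ``index`` (1-based, by distance from mouth),
    axial position ``h`` (>= 0), position angle ``theta`` in degrees in
    ``[0, 360)``, and optionally the 3D coordinates of the tentacle base."""

    index: int
    h: float
    theta: float
    xyz: Optional[Tuple[float, float, float]] = None

    def __post_init__(self):
        if self.index < 1:
            raise ValueError(f"tentacle index must be >= 1, got {self.index}")
        if not np.isfinite(self.h) or self.h < 0:
            raise ValueError(f"axial position h must be finite and >= 0, got {self.h}")
        object.__setattr__(self, "theta", normalize_angle(self.theta))
        if self.xyz is not None:
            x, y, z = self.xyz
            if not all(np.isfinite(v) for v in (x, y, z)):
                raise ValueError(f"non-finite xyz for tentacle {self.index}")
            object.__setattr__(self, "xyz", (float(x), float(y), float(z)))


@dataclass
class PolypArrangement:
    """All tentacles of one polyp, sorted ascending by ``(h, theta)``.

    The sort is stable: equal ``(h, theta)`` pairs keep their input order.
    ``diameter`` is the body diameter at the primary-ring level (optional,
    same unit as ``h`` unless stated otherwise by ``unit``).
    """

    polyp_id: str
    tentacles: Sequence[TentacleRecord]
    diameter: Optional[float] = None
    unit: str = "um"

    def __post_init__(self):
        if len(self.tentacles) == 0:
            raise ValueError(f"polyp {self.polyp_id!r} has no tentacles")
        if self.diameter is not None and not self.diameter > 0:
            raise ValueError(
                f"polyp {self.polyp_id!r}: diameter must be positive, got {self.diameter}"
            )
        idx = [t.index for t in self.tentacles]
        if len(set(idx)) != len(idx):
            dupes = sorted({i for i in idx if idx.count(i) > 1})
            raise IntegrityError(
                f"polyp {self.polyp_id!r}: duplicate tentacle index(es) {dupes}"
            )
        self.tentacles = sorted(self.tentacles, key=lambda t: (t.h, t.theta))

    @property
    def m(self) -> int:
        """Tentacle count."""
        return len(self.tentacles)

    @property
    def h(self) -> np.ndarray:
        return np.array([t.h for t in self.tentacles], dtype=float)

    @property
    def theta(self) -> np.ndarray:
        return np.array([t.theta for t in self.tentacles], dtype=float)


@dataclass
class SimSnapshot:
    """State of the three morphogen fields on the cylindrical lattice.

    ``a``, ``b``, ``c`` are ``(L, W)`` arrays (axial row 0 = oral end,
    columns wrap around the circumference).  ``tentacle_cells`` lists
    ``(row, col, initiation_step)`` in initiation order; steps are strictly
    increasing because at most one tentacle initiates per time step.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    tentacle_cells: Sequence[Tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        shapes = {f.shape for f in (self.a, self.b, self.c)}
        if len(shapes) != 1:
            raise ValueError(f"field shapes differ: {shapes}")
        for name, f in (("a", self.a), ("b", self.b), ("c", self.c)):
            if np.any(f < 0):
                raise ValueError(f"negative concentration in field {name}")
        cells = [(r, c) for r, c, _ in self.tentacle_cells]
        if len(set(cells)) != len(cells):
            raise IntegrityError("duplicate tentacle cells in snapshot")
        steps = [s for _, _, s in self.tentacle_cells]
        if any(s2 <= s1 for s1, s2 in zip(steps, steps[1:])):
            raise IntegrityError("tentacle initiation steps must strictly increase")

    @property
    def geometry(self) -> Tuple[int, int]:
        """(circumference W in cells, axial length L in cells)."""
        L, W = self.a.shape
        return (W, L)
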
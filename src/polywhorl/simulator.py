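"""Three-morphogen reaction-diffusion model of tentacle initiation on a
cylindrical body surface.

Model
-----
Three diffusible substances evolve on a W x L cell lattice wrapped into a
cylinder (periodic circumferentially, zero-flux at the oral and aboral
ends):

* activator ``a`` — secreted at a constant rate in the mouth rows, enables
  initiation where ``a > T_a``;
* inhibitor ``b`` — also mouth-derived, vetoes initiation near the mouth
  where ``b >= T_i``;
* lateral inhibitor ``c`` — secreted by every existing tentacle, vetoes
  initiation where ``c >= T_ti`` and thereby enforces the spacing between
  tentacles and between successive rings.

Each field obeys  ``df/dt = D lap(f) - k f + s``  with its own diffusion
coefficient, first-order decay and source, integrated by explicit Euler at
a step below the stability bound ``dt <= 1/(4 max D + max k)``.

A cell becomes a tentacle when it is in the body region (not mouth), all
three threshold conditions hold, and it carries the *global maximum* of
the activator among eligible cells; at most one tentacle initiates per
check, and a tentacle is permanent (a lasting point source of ``c``).
Because the activator decays aborally, the global-maximum rule initiates
tentacles sequentially from the oral side: a ring fills at the spacing set
by the lateral-inhibition range, then initiation moves one ring further
aborally, with each ring angularly offset by half a period from the ring
above (alternation).  The tentacle count per ring is the number of spacing
lengths that fit around the circumference, which is how body diameter
selects tri-, tetra- or pentaradial symmetry.

Timing
------
Eligibility is evaluated every ``init_interval`` Euler steps rather than
every step: the lateral inhibitor needs a diffusion time of order
``r^2 / 4 D_c`` to establish its blocking radius ``r`` around a fresh
tentacle, and checking faster than that lets tentacles pile up at
sub-spacing distances.  An initial competence delay ``init_warmup``
precedes the first check so that the mouth gradients mature; during the
delay the seeded initial noise is diffusion-smoothed to its longest
circumferential wavelength, which makes the activator maximum a smooth
function of angle and the resulting packing deterministic up to a rigid
rotation set by the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import PolypArrangement, SimSnapshot, TentacleRecord
from .errors import CalibrationError, GeometryError, NumericalInstabilityError

__all__ = [
    "SimParams",
    "SimState",
    "laplacian_cylinder",
    "euler_step",
    "try_initiate",
    "run_simulation",
    "calibrate_params",
    "arrangement_from_state",
    "stability_bound",
]


@dataclass(frozen=True)
class SimParams:
    """All rate, threshold and geometry constants of the model.

    Defaults are the calibration output committed with the package
    (re-derived, not transcribed): at circumferences W = 54, 72 and 90
    cells they produce primary rings of 3, 4 and 5 tentacles with ~18-cell
    spacing, periodic rings down the body and half-period alternation.
    """

    # diffusion (lattice^2 / time), decay (1 / time), sources (conc / time)
    D_a: float = 3.0
    D_b: float = 3.0
    D_c: float = 3.0
    k_a: float = 0.0075
    k_b: float = 0.12
    k_c: float = 12.0
    s_a: float = 1.0
    s_b: float = 1.0
    s_c: float = 1.0
    # initiation thresholds (conc)
    T_a: float = 0.2
    T_i: float = 1.1
    T_ti: float = 4.71e-16
    # geometry (cells)
    W: int = 72
    L: int = 80
    mouth_rows: int = 2
    # time stepping
    dt: Optional[float] = None      # None -> dt_fraction of the stability bound
    dt_fraction: float = 0.8
    max_steps: int = 22000
    max_tentacles: int = 26
    init_warmup: int = 2400         # steps before the first eligibility check
    init_interval: int = 700        # steps between eligibility checks
    # initial condition
    noise_amp: float = 2e-4
    seed: int = 0

    def __post_init__(self):
        for name in ("D_a", "D_b", "D_c", "k_a", "k_b", "k_c",
                     "s_a", "s_b", "s_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("T_a", "T_i", "T_ti"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.W < 3 or self.L < 3:
            raise GeometryError(f"lattice too small: W={self.W}, L={self.L}")
        if not 1 <= self.mouth_rows < self.L:
            raise ValueError("mouth_rows must satisfy 1 <= mouth_rows < L")
        bound = stability_bound(self)
        if self.effective_dt > bound:
            raise NumericalInstabilityError(
                f"dt={self.effective_dt:g} exceeds the explicit-scheme "
                f"stability bound 1/(4 max D + max k) = {bound:g}"
            )

    @property
    def effective_dt(self) -> float:
        if self.dt is not None:
            return self.dt
        bound = stability_bound(self)
        if not np.isfinite(bound):
            raise ValueError("all rates are zero: specify dt explicitly")
        return self.dt_fraction * bound


def stability_bound(params: SimParams) -> float:
    """dt bound of the explicit scheme: ``1 / (4 max(D) + max(k))``."""
    d = max(params.D_a, params.D_b, params.D_c)
    k = max(params.k_a, params.k_b, params.k_c)
    denom = 4.0 * d + k
    return float("inf") if denom == 0.0 else 1.0 / denom


@dataclass
class SimState:
    """Mutable simulation state: the three fields, tentacle list, step."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    tentacles: List[Tuple[int, int, int]] = field(default_factory=list)
    step: int = 0

    @property
    def tentacle_mask(self) -> np.ndarray:
        mask = np.zeros(self.a.shape, dtype=bool)
        for r, c, _ in self.tentacles:
            mask[r, c] = True
        return mask

    def snapshot(self) -> SimSnapshot:
        return SimSnapshot(
            a=self.a.copy(), b=self.b.copy(), c=self.c.copy(),
            tentacle_cells=list(self.tentacles),
        )


def initial_state(params: SimParams, rng: Optional[np.random.Generator] = None) -> SimState:
    """Zero fields plus seeded uniform noise of amplitude ``noise_amp``."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    shape = (params.L, params.W)
    return SimState(
        a=rng.uniform(0.0, params.noise_amp, shape),
        b=rng.uniform(0.0, params.noise_amp, shape),
        c=rng.uniform(0.0, params.noise_amp, shape),
    )


def laplacian_cylinder(f: np.ndarray) -> np.ndarray:
    """Five-point discrete Laplacian on the cylinder.

    Columns wrap (periodic circumference); rows use zero-flux (Neumann)
    boundaries at the oral and aboral ends via mirrored ghost rows, so the
    Laplacian of any field sums to zero exactly.
    """
    L, W = f.shape
    if W < 3 or L < 3:
        raise GeometryError(f"lattice too small for the 5-point stencil: W={W}, L={L}")
    up = np.empty_like(f)
    dn = np.empty_like(f)
    up[1:] = f[:-1]
    up[0] = f[0]          # ghost row mirrors the boundary row: zero flux
    dn[:-1] = f[1:]
    dn[-1] = f[-1]
    return up + dn + np.roll(f, 1, axis=1) + np.roll(f, -1, axis=1) - 4.0 * f


def _mouth_mask(params: SimParams) -> np.ndarray:
    m = np.zeros((params.L, params.W), dtype=bool)
    m[: params.mouth_rows] = True
    return m


def euler_step(state: SimState, params: SimParams,
               mouth: Optional[np.ndarray] = None,
               tentacle_mask: Optional[np.ndarray] = None) -> SimState:
    """Advance all three fields by one explicit Euler step (in place).

    Sources: ``s_a`` and ``s_b`` on the mouth rows, ``s_c`` on tentacle
    cells.  Raises :class:`NumericalInstabilityError` naming the field and
    step if any field goes non-finite.
    """
    dt = params.effective_dt
    if mouth is None:
        mouth = _mouth_mask(params)
    if tentacle_mask is None:
        tentacle_mask = state.tentacle_mask
    state.a += dt * (params.D_a * laplacian_cylinder(state.a)
                     - params.k_a * state.a + params.s_a * mouth)
    state.b += dt * (params.D_b * laplacian_cylinder(state.b)
                     - params.k_b * state.b + params.s_b * mouth)
    state.c += dt * (params.D_c * laplacian_cylinder(state.c)
                     - params.k_c * state.c + params.s_c * tentacle_mask)
    state.step += 1
    for name, f in (("a", state.a), ("b", state.b), ("c", state.c)):
        if not np.isfinite(f[0, 0]) or not np.all(np.isfinite(f)):
            raise NumericalInstabilityError(
                f"field {name!r} became non-finite at step {state.step}"
            )
    return state


def try_initiate(state: SimState, params: SimParams,
                 body: Optional[np.ndarray] = None,
                 tentacle_mask: Optional[np.ndarray] = None) -> Optional[Tuple[int, int]]:
    """Initiate at most one tentacle.

    Among body cells (mouth rows and existing tentacles excluded) with
    ``a > T_a``, ``b < T_i`` and ``c < T_ti``, the cell with the globally
    maximal activator becomes a tentacle.  Equal maxima break toward the
    lowest ``(row, col)`` for determinism.  Returns the new cell or None.
    """
    if body is None:
        body = ~_mouth_mask(params)
    if tentacle_mask is None:
        tentacle_mask = state.tentacle_mask
    eligible = (body & ~tentacle_mask
                & (state.a > params.T_a)
                & (state.b < params.T_i)
                & (state.c < params.T_ti))
    if not eligible.any():
        return None
    masked = np.where(eligible, state.a, -np.inf)
    row, col = np.unravel_index(int(np.argmax(masked)), masked.shape)
    cell = (int(row), int(col))
    state.tentacles.append((cell[0], cell[1], state.step))
    return cell


def run_simulation(
    params: SimParams,
    initial_noise: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
) -> Tuple[SimState, Optional[PolypArrangement]]:
    """Run the model to ``max_steps`` or ``max_tentacles``.

    ``initial_noise`` overrides the seeded initial fields (used by the
    rotation-equivariance tests).  Returns the final state and the
    resulting arrangement (h = axial row, theta = 360 col / W, xyz on the
    cylinder of diameter W / pi), or ``None`` when no tentacle initiated.
    """
    if initial_noise is not None:
        a0, b0, c0 = (np.array(f, dtype=float, copy=True) for f in initial_noise)
        state = SimState(a=a0, b=b0, c=c0)
    else:
        state = initial_state(params)
    mouth = _mouth_mask(params)
    body = ~mouth
    tentacle_mask = np.zeros((params.L, params.W), dtype=bool)
    for _ in range(params.max_steps):
        euler_step(state, params, mouth=mouth, tentacle_mask=tentacle_mask)
        if state.step >= params.init_warmup and state.step % params.init_interval == 0:
            cell = try_initiate(state, params, body=body, tentacle_mask=tentacle_mask)
            if cell is not None:
                tentacle_mask[cell] = True
                if len(state.tentacles) >= params.max_tentacles:
                    break
    arr = arrangement_from_state(state, params) if state.tentacles else None
    return state, arr


def arrangement_from_state(state: SimState, params: SimParams,
                           polyp_id: Optional[str] = None) -> PolypArrangement:
    """Export the tentacle pattern as a ``PolypArrangement`` in lattice
    units (h = row index = axial distance from the oral end)."""
    if polyp_id is None:
        polyp_id = f"sim_W{params.W}_seed{params.seed}"
    radius = params.W / (2.0 * np.pi)
    ordered = sorted(state.tentacles, key=lambda t: (t[0], 360.0 * t[1] / params.W))
    records = []
    for i, (row, col, _) in enumerate(ordered, start=1):
        theta = 360.0 * col / params.W
        rad = np.deg2rad(theta)
        records.append(
            TentacleRecord(
                index=i, h=float(row), theta=theta,
                xyz=(radius * np.cos(rad), radius * np.sin(rad), float(row)),
            )
        )
    if not records:
        raise ValueError("simulation produced no tentacles")
    return PolypArrangement(
        polyp_id=polyp_id, tentacles=records,
        diameter=params.W / np.pi, unit="cells",
    )


def primary_ring_count(arr: PolypArrangement) -> int:
    """Primary-ring tentacle count of an arrangement (convenience)."""
    from .metrics import detect_rings, internode_lengths

    return detect_rings(internode_lengths(arr)).primary_count


def calibrate_params(
    ell_values: Sequence[float],
    tti_values: Sequence[float],
    base: Optional[SimParams] = None,
    geometries: Sequence[int] = (54, 72, 90),
    targets: Sequence[int] = (3, 4, 5),
    seeds: Sequence[int] = (1, 2, 3),
    min_successes: int = 2,
) -> SimParams:
    """Grid-search the lateral-inhibition length ``sqrt(D_c/k_c)`` and the
    tentacle-inhibitor threshold ``T_ti``.

    A candidate passes when each geometry yields its target primary-ring
    count in at least ``min_successes`` of the seeded replicates.  Returns
    the first passing parameter set (smallest grid point); raises
    :class:`CalibrationError` carrying the best candidate otherwise.
    ``ell`` is applied by adjusting ``k_c = D_c / ell^2``.
    """
    if base is None:
        base = SimParams()
    best = None
    best_score = -1
    report = []
    for ell, tti in itertools.product(ell_values, tti_values):
        cand = replace(base, k_c=base.D_c / ell ** 2, T_ti=tti)
        score = 0
        ok = True
        for w, target in zip(geometries, targets):
            hits = 0
            for s in seeds:
                p = replace(cand, W=int(w), seed=int(s))
                _, arr = run_simulation(p)
                if primary_ring_count(arr) == target:
                    hits += 1
            score += hits
            if hits < min_successes:
                ok = False
        report.append({"ell": ell, "T_ti": tti, "score": score})
        if score > best_score:
            best_score, best = score, cand
        if ok:
            return cand
    raise CalibrationError(
        f"no candidate met the {targets} targets in >= {min_successes} "
        f"of {len(seeds)} replicates per geometry",
        best_candidate=best, report=report,
    )
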
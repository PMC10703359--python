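"""End-to-end flows: quantify a table of arrangements, or simulate and
feed the result through the same quantification stages.

Every analysis constant (gap multiplier, lag range, period-call threshold,
minimum tentacle count) is surfaced in :class:`RunConfig`; there are no
hidden constants.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import pandas as pd

from .circular import angle_stats
from .datamodel import PolypArrangement
from .errors import ClassificationError, UndefinedStatisticError
from .metrics import (alternation_offsets, detect_rings, internode_lengths,
                      nearest_angles_within_ring)
from .periodicity import (DEFAULT_MAX_LAG, DEFAULT_MIN_TENTACLES,
                          DEFAULT_R_THRESHOLD, NOT_SIGNIFICANT,
                          cross_classify, lag_correlations)
from .population import (SymmetryCall, adjacent_distances_3d,
                         size_symmetry_analysis, tally_symmetries)
from .simulator import SimParams, run_simulation

log = logging.getLogger("polywhorl")

__all__ = ["RunConfig", "quantify", "simulate_then_quantify", "QuantifyResult"]


@dataclass(frozen=True)
class RunConfig:
    """Analysis constants with their observational defaults."""

    gap_multiplier: float = 2.0
    max_lag: int = DEFAULT_MAX_LAG
    r_threshold: float = DEFAULT_R_THRESHOLD
    min_tentacles: int = DEFAULT_MIN_TENTACLES
    seed: int = 0

    def __post_init__(self):
        if self.gap_multiplier <= 0 or self.r_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")


@dataclass
class QuantifyResult:
    """The four report tables of a quantification run."""

    metrics: pd.DataFrame       # per-polyp, per-ring statistics
    contingency: pd.DataFrame   # primary count x period call
    tally: pd.DataFrame         # class, count, percent
    correlations: pd.DataFrame  # label, r, n

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.metrics.to_csv(os.path.join(outdir, "metrics.tsv"), sep="\t",
                            index=False, float_format="%.6g")
        self.contingency.to_csv(os.path.join(outdir, "contingency.tsv"), sep="\t")
        self.tally.to_csv(os.path.join(outdir, "tally.tsv"), sep="\t", index=False)
        self.correlations.to_csv(os.path.join(outdir, "correlations.tsv"), sep="\t",
                                 index=False, float_format="%.6g")


def _polyp_rows(arr: PolypArrangement, config: RunConfig) -> List[dict]:
    """Per-ring metric rows for one polyp; empty-ish when m < 2."""
    rows = []
    if arr.m < 2:
        log.warning("polyp %s: single tentacle, no metrics", arr.polyp_id)
        return rows
    partition = detect_rings(internode_lengths(arr), gap_multiplier=config.gap_multiplier)
    if partition.no_gap:
        log.info("polyp %s: no ring-defining gap (non-whorled)", arr.polyp_id)
    offsets = {}
    if len(partition.rings) >= 2:
        for k, off in enumerate(alternation_offsets(arr, partition), start=1):
            offsets[k] = off.value_deg
    for k, ring in enumerate(partition.rings):
        if len(ring) >= 2:
            st = angle_stats(nearest_angles_within_ring(arr, ring))
            mean, sd = st.mean, st.circ_sd
        else:
            mean, sd = None, None
        rows.append(
            {
                "polyp_id": arr.polyp_id,
                "ring": k,
                "count": len(ring),
                "mean_angle": mean,
                "circ_sd": sd,
                "alternation_offset": offsets.get(k),
                "no_gap": partition.no_gap,
            }
        )
    return rows


def quantify(arrangements: Sequence[PolypArrangement],
             config: RunConfig = RunConfig()) -> QuantifyResult:
    """Run the full quantification: ring metrics, periodicity
    cross-classification, symmetry tallies and size correlations."""
    metric_rows: List[dict] = []
    calls: List[SymmetryCall] = []
    diameters: List[Optional[float]] = []
    mean_dists: List[Optional[float]] = []
    for arr in arrangements:
        metric_rows.extend(_polyp_rows(arr, config))
        if arr.m < 2:
            continue
        partition = detect_rings(internode_lengths(arr),
                                 gap_multiplier=config.gap_multiplier)
        if partition.no_gap:
            continue
        call = NOT_SIGNIFICANT
        if arr.m >= config.min_tentacles:
            try:
                call = lag_correlations(
                    internode_lengths(arr), max_lag=config.max_lag,
                    r_threshold=config.r_threshold,
                ).call
            except ClassificationError:
                log.info("polyp %s: periodicity undefined", arr.polyp_id)
        calls.append(SymmetryCall(arr.polyp_id, partition.primary_count, call))
        diameters.append(arr.diameter)
        if arr.diameter is None:
            log.info("polyp %s: missing diameter", arr.polyp_id)
        try:
            dists = adjacent_distances_3d(arr, partition.primary_ring)
            mean_dists.append(sum(dists) / len(dists))
        except ValueError:
            mean_dists.append(None)

    metrics = pd.DataFrame(
        metric_rows,
        columns=["polyp_id", "ring", "count", "mean_angle", "circ_sd",
                 "alternation_offset", "no_gap"],
    )
    contingency = cross_classify(
        arrangements, min_tentacles=config.min_tentacles,
        max_lag=config.max_lag, r_threshold=config.r_threshold,
        gap_multiplier=config.gap_multiplier,
    )
    tally = (tally_symmetries(calls) if calls
             else pd.DataFrame(columns=["primary_count", "symmetry", "count", "percent"]))
    corr_rows = []
    try:
        res = size_symmetry_analysis(calls, diameters, mean_dists)
        for label, cr in res.items():
            corr_rows.append({"label": f"symmetry_vs_{label}", "r": cr.r, "n": cr.n})
    except (ValueError, UndefinedStatisticError) as exc:
        log.info("size-symmetry correlation skipped: %s", exc)
    correlations = pd.DataFrame(corr_rows, columns=["label", "r", "n"])
    return QuantifyResult(metrics=metrics, contingency=contingency,
                          tally=tally, correlations=correlations)


def simulate_then_quantify(
    sim_params: SimParams,
    geometries: Sequence[int] = (54, 72, 90),
    seeds: Sequence[int] = (1, 2, 3),
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Run the simulator over geometries x seeds and quantify each run.

    Returns one row per run: circumference, seed, tentacle count,
    primary-ring count, primary-ring circular mean and SD, period call,
    first alternation offset.  The period call uses the run's own tentacle
    count as the minimum (simulated polyps are noise-free, so the
    observational >= 20 restriction is not informative here).
    """
    rows = []
    for w in geometries:
        for s in seeds:
            p = replace(sim_params, W=int(w), seed=int(s))
            _, arr = run_simulation(p)
            if arr is None:
                raise RuntimeError(f"simulation at W={w}, seed={s} produced no tentacles")
            series = internode_lengths(arr)
            partition = detect_rings(series, gap_multiplier=config.gap_multiplier)
            st = angle_stats(nearest_angles_within_ring(arr, partition.primary_ring))
            try:
                call = lag_correlations(series, max_lag=config.max_lag,
                                        r_threshold=config.r_threshold).call
            except ClassificationError:
                call = NOT_SIGNIFICANT
            offset = None
            if len(partition.rings) >= 2:
                offset = alternation_offsets(arr, partition)[0].value_deg
            rows.append(
                {
                    "circumference": w,
                    "seed": s,
                    "tentacles": arr.m,
                    "primary_count": partition.primary_count,
                    "primary_mean_angle": st.mean,
                    "primary_circ_sd": st.circ_sd,
                    "period_call": call,
                    "alternation_offset": offset,
                }
            )
    return pd.DataFrame(rows)
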
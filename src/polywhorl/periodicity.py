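"""Whole-body periodicity classification by lag correlation.

If ring-defining gaps recur every ``x`` tentacles, the internode sequence
``dh_1 .. dh_{m-1}`` correlates strongly with itself shifted by ``x``.
``R_k`` is the Pearson correlation of ``(dh_1..dh_{m-1-k})`` with
``(dh_{1+k}..dh_{m-1})`` for lags ``k = 1..8``; the lag maximising ``R_k``
is the period candidate, accepted when ``max R_k > 0.5`` and the
correlation is significant (p <= 0.05, two-sided t-approximation with
``n-2`` degrees of freedom on the overlap length).  Otherwise the polyp is
called "n.s.".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import PolypArrangement
from .errors import ClassificationError
from .metrics import InternodeSeries, detect_rings, internode_lengths

__all__ = [
    "PeriodicityResult",
    "lag_correlations",
    "classify_period",
    "cross_classify",
    "NOT_SIGNIFICANT",
    "DEFAULT_MAX_LAG",
    "DEFAULT_R_THRESHOLD",
    "DEFAULT_MIN_TENTACLES",
]

NOT_SIGNIFICANT = "n.s."
DEFAULT_MAX_LAG = 8
DEFAULT_R_THRESHOLD = 0.5
#: a whorl of period p correlates equally at lags p, 2p, ...; lags whose
#: R_k is within this band of the maximum are treated as equivalent and
#: the smallest one (the fundamental period) is called
DEFAULT_TIE_TOLERANCE = 0.02
#: classification is restricted to polyps with at least this many tentacles
DEFAULT_MIN_TENTACLES = 20

PeriodCall = Union[int, str]


@dataclass
class PeriodicityResult:
    """Lag correlations and the resulting period call for one polyp.

    ``r_by_lag`` maps each lag with a defined correlation to ``R_k``; lags
    with zero variance in either subsequence are absent.  ``call`` is the
    best lag when ``max_r > r_threshold`` and ``p_value <= 0.05``, else
    ``"n.s."``.
    """

    r_by_lag: Dict[int, float]
    best_k: int
    max_r: float
    p_value: float
    call: PeriodCall
    n_overlap: int


def _pearson(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def _p_value(r: float, n: int) -> float:
    """Two-sided p for Pearson r via the t-approximation, df = n - 2."""
    if n <= 2:
        return 1.0
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def lag_correlations(
    series: InternodeSeries,
    max_lag: int = DEFAULT_MAX_LAG,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> PeriodicityResult:
    """Compute ``R_k`` for k = 1..max_lag and classify the period.

    Each lag needs at least 3 overlapping internode pairs; lags with an
    undefined correlation (zero variance) are excluded from the argmax.
    Ties in the argmax break toward the smallest lag — the smallest period
    consistent with the data.

    Raises :class:`ClassificationError` when every lag is undefined
    (e.g. a constant internode sequence).
    """
    dh = np.asarray(series.values, dtype=float)
    r_by_lag: Dict[int, float] = {}
    n_by_lag: Dict[int, int] = {}
    for k in range(1, max_lag + 1):
        if dh.size - k < 3:
            continue
        r = _pearson(dh[:-k], dh[k:])
        if r is not None:
            r_by_lag[k] = r
            n_by_lag[k] = dh.size - k
    if not r_by_lag:
        raise ClassificationError(
            "periodicity undefined: no lag has a defined correlation "
            "(constant internode sequence or too few tentacles)"
        )
    top = max(r_by_lag.values())
    # exact near-ties break toward the smallest lag
    best_k = min(k for k, r in r_by_lag.items() if r >= top - tie_tolerance)
    max_r = r_by_lag[best_k]
    n = n_by_lag[best_k]
    p = _p_value(max_r, n)
    if max_r > r_threshold and p <= 0.05:
        # a period-p whorl also correlates at lags 2p, 3p, ...; when the
        # argmax lands on a harmonic whose divisor clears the same bar,
        # the fundamental period (the divisor) is the call
        call: PeriodCall = best_k
        for d in range(1, best_k):
            if best_k % d == 0 and d in r_by_lag and r_by_lag[d] > r_threshold \
                    and _p_value(r_by_lag[d], n_by_lag[d]) <= 0.05:
                call = d
                break
    else:
        call = NOT_SIGNIFICANT
    return PeriodicityResult(
        r_by_lag=r_by_lag, best_k=best_k, max_r=max_r, p_value=p, call=call,
        n_overlap=n,
    )


def classify_period(result: PeriodicityResult,
                    r_threshold: float = DEFAULT_R_THRESHOLD) -> PeriodCall:
    """Period call from an existing result: the (harmonic-resolved) period
    when ``max_r > r_threshold`` and ``p <= 0.05``, else ``"n.s."``."""
    if result.max_r > r_threshold and result.p_value <= 0.05:
        return result.call if result.call != NOT_SIGNIFICANT else result.best_k
    return NOT_SIGNIFICANT


UNRINGED = "unringed"


def cross_classify(
    polyps: Sequence[PolypArrangement],
    min_tentacles: int = DEFAULT_MIN_TENTACLES,
    max_lag: int = DEFAULT_MAX_LAG,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    gap_multiplier: float = 2.0,
) -> pd.DataFrame:
    """Contingency table of primary-ring count versus period call.

    Rows are primary-ring counts (with an ``"unringed"`` margin for polyps
    whose partition has no ring-defining gap), columns are period calls
    (integers and ``"n.s."``), cells are polyp counts, with row/column
    totals.  Polyps with fewer than ``min_tentacles`` tentacles are
    excluded, mirroring the restriction under which the classification is
    meaningful.
    """
    pairs: List[Tuple[Union[int, str], PeriodCall]] = []
    for arr in polyps:
        if arr.m < max(2, min_tentacles):
            continue
        series = internode_lengths(arr)
        partition = detect_rings(series, gap_multiplier=gap_multiplier)
        row_key: Union[int, str] = UNRINGED if partition.no_gap else partition.primary_count
        try:
            res = lag_correlations(series, max_lag=max_lag, r_threshold=r_threshold)
            call = res.call
        except ClassificationError:
            call = NOT_SIGNIFICANT
        pairs.append((row_key, call))

    if not pairs:
        return pd.DataFrame({"Total": {"Total": 0}})
    df = pd.DataFrame(pairs, columns=["primary", "period"])
    table = pd.crosstab(df["primary"], df["period"], margins=True, margins_name="Total")
    return table
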
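"""Readers and writers for arrangement tables and simulator snapshots.

The arrangement table is a UTF-8 TSV with header
``polyp_id  index  h  theta  x  y  z  diameter`` (x, y, z, diameter may be
empty).  One :class:`~polywhorl.datamodel.PolypArrangement` is produced per
distinct ``polyp_id``; angles are normalised into [0, 360) and records are
sorted by ``(h, theta)``.

Snapshots are written as one ``row  col  value`` TSV per morphogen field
plus a ``row  col  step`` TSV for tentacle initiation events.
"""

from __future__ import annotations

import math
import os
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import PolypArrangement, SimSnapshot, TentacleRecord
from .errors import FormatError, IntegrityError

__all__ = [
    "read_arrangements",
    "write_arrangements",
    "write_snapshot",
    "read_snapshot",
    "load_yaml_config",
    "ARRANGEMENT_COLUMNS",
]

ARRANGEMENT_COLUMNS = ["polyp_id", "index", "h", "theta", "x", "y", "z", "diameter"]
_REQUIRED = ["polyp_id", "index", "h", "theta"]


def read_arrangements(path: os.PathLike | str, unit: str = "um") -> List[PolypArrangement]:
    """Read an arrangement TSV into one ``PolypArrangement`` per polyp.

    Raises
    ------
    FormatError
        if a required column is missing.
    ValueError
        if an angle or axial position cannot be normalised (non-finite),
        with the offending 1-based data row number in the message.
    IntegrityError
        on a duplicate ``(polyp_id, index)`` pair.
    """
    df = pd.read_csv(path, sep="\t", dtype={"polyp_id": str})
    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"arrangement table {path}: missing required column {col!r}")
    dup = df.duplicated(subset=["polyp_id", "index"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["polyp_id", "index"]].drop_duplicates().values.tolist()
        raise IntegrityError(f"duplicate (polyp_id, index) pairs: {pairs}")

    arrangements = []
    for pid, grp in df.groupby("polyp_id", sort=True):
        records = []
        for row_number, row in zip(grp.index + 1, grp.to_dict("records")):
            try:
                rec = TentacleRecord(
                    index=int(row["index"]),
                    h=float(row["h"]),
                    theta=float(row["theta"]),
                    xyz=_xyz_of(row),
                )
            except ValueError as exc:
                raise ValueError(f"{path} data row {row_number}: {exc}") from exc
            records.append(rec)
        diameter = None
        if "diameter" in grp.columns:
            d = grp["diameter"].dropna()
            if len(d):
                diameter = float(d.iloc[0])
        arrangements.append(
            PolypArrangement(polyp_id=str(pid), tentacles=records, diameter=diameter, unit=unit)
        )
    return arrangements


def _xyz_of(row: dict) -> Optional[tuple]:
    vals = [row.get(k) for k in ("x", "y", "z")]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        return None
    return tuple(float(v) for v in vals)


def write_arrangements(arrangements: Sequence[PolypArrangement], path: os.PathLike | str) -> None:
    """Write arrangements to TSV; ``read_arrangements`` round-trips the
    result up to float formatting. An empty list yields a header-only file."""
    rows = []
    for arr in arrangements:
        for t in arr.tentacles:
            x, y, z = t.xyz if t.xyz is not None else (None, None, None)
            rows.append(
                {
                    "polyp_id": arr.polyp_id,
                    "index": t.index,
                    "h": t.h,
                    "theta": t.theta,
                    "x": x,
                    "y": y,
                    "z": z,
                    "diameter": arr.diameter,
                }
            )
    df = pd.DataFrame(rows, columns=ARRANGEMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_snapshot(snapshot: SimSnapshot, outdir: os.PathLike | str) -> None:
    """Write one ``row col value`` TSV per field and a tentacle-event TSV."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    for name in ("a", "b", "c"):
        f = getattr(snapshot, name)
        L, W = f.shape
        rows, cols = np.meshgrid(np.arange(L), np.arange(W), indexing="ij")
        pd.DataFrame(
            {"row": rows.ravel(), "col": cols.ravel(), "value": f.ravel()}
        ).to_csv(os.path.join(outdir, f"field_{name}.tsv"), sep="\t", index=False,
                 float_format="%.10g")
    pd.DataFrame(
        snapshot.tentacle_cells, columns=["row", "col", "step"]
    ).to_csv(os.path.join(outdir, "tentacles.tsv"), sep="\t", index=False)


def read_snapshot(outdir: os.PathLike | str) -> SimSnapshot:
    """Inverse of :func:`write_snapshot`."""
    outdir = str(outdir)
    fields: Dict[str, np.ndarray] = {}
    for name in ("a", "b", "c"):
        df = pd.read_csv(os.path.join(outdir, f"field_{name}.tsv"), sep="\t")
        L = int(df["row"].max()) + 1
        W = int(df["col"].max()) + 1
        f = np.zeros((L, W))
        f[df["row"].to_numpy(), df["col"].to_numpy()] = df["value"].to_numpy()
        fields[name] = f
    tdf = pd.read_csv(os.path.join(outdir, "tentacles.tsv"), sep="\t")
    cells = [tuple(int(v) for v in row) for row in tdf.to_numpy()]
    return SimSnapshot(a=fields["a"], b=fields["b"], c=fields["c"], tentacle_cells=cells)


def load_yaml_config(path: os.PathLike | str) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        out = yaml.safe_load(fh)
    if out is None:
        return {}
    if not isinstance(out, dict):
        raise FormatError(f"config {path}: expected a mapping at top level")
    return out
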
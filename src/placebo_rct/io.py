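"""Plain-text I/O for every pipeline artifact.

All files are UTF-8 CSV/TSV with a header row; timestamps are ISO-8601.
Readers validate eagerly and report the offending line number; writers
round-trip values at full precision (repr-level floats).

Formats
-------
ratings.csv         subject_id, timestamp, vas
visits.csv          subject_id, visit_1 .. visit_6
questionnaires.csv  subject_id, <one column per subscale>
volumes.csv         subject_id, visit, NAc_L/R, AMY_L/R, HIP_L/R, covariates
matrix files        whitespace-delimited square numeric text, one per
                    subject-visit, with a newline-delimited node-id sidecar
masks               newline-delimited node ids
"""

from __future__ import annotations

import logging
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .brain import ConnectivityMatrix
from .ema import RatingSeries

logger = logging.getLogger(__name__)


class DataFormatError(ValueError):
    """Malformed input file; the message names the file and line."""


def write_ratings(ratings: dict[str, RatingSeries], path: str | Path) -> None:
    rows = []
    for sid, series in ratings.items():
        for _, row in series.entries.iterrows():
            rows.append(
                {
                    "subject_id": sid,
                    "timestamp": pd.Timestamp(row["timestamp"]).isoformat(),
                    "vas": repr(float(row["vas"])),
                }
            )
    pd.DataFrame(rows, columns=["subject_id", "timestamp", "vas"]).to_csv(
        path, index=False
    )


def read_ratings(path: str | Path) -> dict[str, RatingSeries]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    expected = ["subject_id", "timestamp", "vas"]
    if list(df.columns) != expected:
        raise DataFormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    parsed = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            ts = datetime.fromisoformat(str(row["timestamp"]))
        except ValueError:
            raise DataFormatError(
                f"{path}:{line}: timestamp {row['timestamp']!r} is not ISO-8601"
            ) from None
        try:
            vas = float(row["vas"])
        except ValueError:
            raise DataFormatError(f"{path}:{line}: vas {row['vas']!r} is not numeric") from None
        if not 0.0 <= vas <= 10.0:
            raise DataFormatError(f"{path}:{line}: vas {vas} outside [0, 10]")
        parsed.append((str(row["subject_id"]), ts, vas))
    out: dict[str, RatingSeries] = {}
    for sid in dict.fromkeys(p[0] for p in parsed):
        entries = pd.DataFrame(
            [(ts, v) for s, ts, v in parsed if s == sid], columns=["timestamp", "vas"]
        )
        out[sid] = RatingSeries(subject_id=sid, entries=entries)
    return out


def write_visits(visits: dict[str, list[datetime]], path: str | Path) -> None:
    cols = [f"visit_{k}" for k in range(1, 7)]
    rows = []
    for sid, dates in visits.items():
        if len(dates) != 6:
            raise ValueError(f"subject {sid}: expected 6 visit dates")
        rows.append({"subject_id": sid, **{c: pd.Timestamp(d).isoformat()
                                           for c, d in zip(cols, dates)}})
    pd.DataFrame(rows, columns=["subject_id", *cols]).to_csv(path, index=False)


def read_visits(path: str | Path) -> dict[str, list[datetime]]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    cols = [f"visit_{k}" for k in range(1, 7)]
    if list(df.columns) != ["subject_id", *cols]:
        raise DataFormatError(f"{path}: expected columns subject_id, {', '.join(cols)}")
    out = {}
    for i, row in df.iterrows():
        line = i + 2
        try:
            dates = [datetime.fromisoformat(str(row[c])) for c in cols]
        except ValueError:
            raise DataFormatError(f"{path}:{line}: non-ISO-8601 visit date") from None
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise DataFormatError(f"{path}:{line}: visit dates not strictly increasing")
        out[str(row["subject_id"])] = dates
    return out


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, index=False, sep=sep, float_format="%.17g")


def read_questionnaires(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns[0] != "subject_id":
        raise DataFormatError(f"{path}: first column must be subject_id")
    return df


def read_volumes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    needed = {"subject_id", "visit", "NAc_L", "NAc_R", "AMY_L", "AMY_R",
              "HIP_L", "HIP_R"}
    missing = needed - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    vol_cols = [c for c in df.columns if c.endswith(("_L", "_R"))]
    bad = df.index[(df[vol_cols] <= 0).any(axis=1)]
    if len(bad):
        raise DataFormatError(f"{path}:{bad[0] + 2}: nonpositive volume")
    return df


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, matrix.weights, fmt="%.17g")
    Path(str(path) + ".nodes").write_text("\n".join(matrix.node_ids) + "\n")


def read_matrix(path: str | Path, space: str = "r") -> ConnectivityMatrix:
    path = Path(path)
    try:
        w = np.loadtxt(path, ndmin=2)
    except ValueError as e:
        raise DataFormatError(f"{path}: non-numeric or ragged matrix payload ({e})") from None
    if w.shape[0] != w.shape[1]:
        raise DataFormatError(f"{path}: matrix is {w.shape[0]}x{w.shape[1]}, not square")
    sidecar = Path(str(path) + ".nodes")
    if sidecar.exists():
        node_ids = sidecar.read_text().split()
    else:
        node_ids = [f"node{i:03d}" for i in range(w.shape[0])]
    if len(node_ids) != w.shape[0]:
        raise DataFormatError(f"{sidecar}: {len(node_ids)} node ids for a "
                              f"{w.shape[0]}-node matrix")
    return ConnectivityMatrix(node_ids=node_ids, weights=w, space=space)


def read_mask(path: str | Path) -> list[str]:
    path = Path(path)
    nodes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(set(nodes)) != len(nodes):
        raise DataFormatError(f"{path}: duplicate node ids in mask")
    return nodes


def write_mask(nodes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(nodes) + "\n")
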
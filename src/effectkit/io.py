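"""CSV readers and report writers.

Supported layouts:

* ``long`` — columns ``group,value``, one row per observation;
* ``summary`` — columns ``mean,sd,n``, one row per group (exactly two);
* ``contingency`` — columns ``a,b,c,d``, a single row (2x2 cell counts);
* ``estimate_se`` — columns ``term,estimate,se``, one row per model term.

Parsing is strict: missing columns, non-numeric cells, and wrong row counts
raise :class:`~effectkit.exceptions.DataError` with row/column context.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .effects import ContingencyTable, TwoGroupSummary
from .exceptions import DataError

__all__ = ["read_table", "write_json", "LAYOUTS"]

LAYOUTS = ("long", "summary", "contingency", "estimate_se")

_REQUIRED = {
    "long": ["group", "value"],
    "summary": ["mean", "sd", "n"],
    "contingency": ["a", "b", "c", "d"],
    "estimate_se": ["term", "estimate", "se"],
}


def _read_csv(path: Union[str, Path], layout: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise DataError(f"{path}: could not parse CSV ({exc})") from exc
    missing = [c for c in _REQUIRED[layout] if c not in df.columns]
    if missing:
        raise DataError(
            f"{path}: layout '{layout}' requires column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return df


def _numeric(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2  # header + 1-based
            raise DataError(f"{path}: missing value in column '{col}' at line {row}")
        if len(bad):
            row = int(bad[0]) + 2
            raise DataError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} in column "
                f"'{col}' at line {row}"
            )
        df[col] = coerced
    return df


def read_table(path: Union[str, Path], layout: str):
    """Read a CSV in one of the supported layouts.

    Returns a DataFrame for ``long`` and ``estimate_se``, a
    :class:`TwoGroupSummary` for ``summary``, and a
    :class:`ContingencyTable` for ``contingency``.
    """
    if layout not in LAYOUTS:
        raise DataError(f"unknown layout '{layout}'; expected one of {LAYOUTS}")
    df = _read_csv(path, layout)

    if layout == "long":
        df = _numeric(df, ["value"], path)
        groups = df["group"].unique()
        if len(groups) < 2:
            raise DataError(f"{path}: long layout needs at least two groups, found {len(groups)}")
        return df

    if layout == "summary":
        df = _numeric(df, ["mean", "sd", "n"], path)
        if len(df) != 2:
            raise DataError(f"{path}: summary layout needs exactly 2 rows, found {len(df)}")
        r1, r2 = df.iloc[0], df.iloc[1]
        return TwoGroupSummary(
            mean1=float(r1["mean"]), sd1=float(r1["sd"]), n1=int(r1["n"]),
            mean2=float(r2["mean"]), sd2=float(r2["sd"]), n2=int(r2["n"]),
        )

    if layout == "contingency":
        df = _numeric(df, ["a", "b", "c", "d"], path)
        if len(df) != 1:
            raise DataError(f"{path}: contingency layout needs exactly 1 row, found {len(df)}")
        r = df.iloc[0]
        return ContingencyTable(a=int(r["a"]), b=int(r["b"]), c=int(r["c"]), d=int(r["d"]))

    df = _numeric(df, ["estimate", "se"], path)
    if (df["se"] <= 0).any():
        row = int(df.index[df["se"] <= 0][0]) + 2
        raise DataError(f"{path}: non-positive standard error at line {row}")
    return df


def write_json(payload: dict, path: Union[str, Path]) -> Path:
    """Write a result record as deterministic (sorted-key) JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True))
    return path


def split_two_groups(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    """Split a long-layout frame into two value arrays (sorted label order)."""
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise DataError(f"expected exactly two groups, found {len(groups)}: {groups}")
    g1 = df.loc[df["group"] == groups[0], "value"].to_numpy(dtype=float)
    g2 = df.loc[df["group"] == groups[1], "value"].to_numpy(dtype=float)
    return g1, g2, (str(groups[0]), str(groups[1]))
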
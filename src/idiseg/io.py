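"""Stable text-file contracts for tract tables, panels and reports.

All files are UTF-8 comma-separated text with a header row and "." decimals.
Tract tables carry one row per census tract: ``city_id, region, tract_id``,
one column per bracket named by its minimum-wage bounds (``mw_0_0.5`` ...
``mw_3_plus``), then ``total``.  Pipeline outputs may start with ``#``
comment lines (used for the run's config hash); readers skip them.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SegregationError, TractTable, bracket_label

_BRACKET_RE = re.compile(r"^mw_([0-9.]+)_([0-9.]+|plus)$")


class TractFileError(SegregationError):
    """Malformed tract-table file."""


def _parse_bracket_columns(columns: Sequence[str]) -> list[tuple[str, float, float]]:
    out = []
    for col in columns:
        m = _BRACKET_RE.match(col)
        if m:
            lo = float(m.group(1))
            hi = math.inf if m.group(2) == "plus" else float(m.group(2))
            out.append((col, lo, hi))
    if not out:
        raise TractFileError("no bracket columns (mw_<lo>_<hi>) found in header")
    los = [lo for _, lo, _ in out]
    if los != sorted(los):
        raise TractFileError(
            "bracket columns must be in ascending-boundary order; got "
            + ", ".join(c for c, _, _ in out)
        )
    return out


def read_tract_tables(path: str | Path) -> list[TractTable]:
    """Read a tract-table file into one ``TractTable`` per city.

    Rejects negative counts and rows whose bracket sum disagrees with the
    ``total`` column, naming the offending tract and line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise TractFileError(f"{path}: empty input file") from None
    if df.empty:
        raise TractFileError(f"{path}: no data rows")
    required = {"city_id", "region", "tract_id", "total"}
    missing = required - set(df.columns)
    if missing:
        raise TractFileError(f"{path}: missing columns {sorted(missing)}")
    brackets = _parse_bracket_columns(list(df.columns))
    bcols = [c for c, _, _ in brackets]
    counts = df[bcols].to_numpy()
    if (counts < 0).any():
        bad = df.index[(counts < 0).any(axis=1)][0]
        raise TractFileError(
            f"{path}: negative count at line {bad + 2} "
            f"(tract {df.loc[bad, 'tract_id']!r})"
        )
    sums = counts.sum(axis=1)
    mismatch = sums != df["total"].to_numpy()
    if mismatch.any():
        bad = df.index[mismatch][0]
        raise TractFileError(
            f"{path}: bracket sum {sums[bad]} != total {df.loc[bad, 'total']} "
            f"at line {bad + 2} (tract {df.loc[bad, 'tract_id']!r})"
        )
    tables = []
    for city_id, sub in df.groupby("city_id", sort=True):
        regions = sub["region"].unique()
        tables.append(
            TractTable(
                city_id=str(city_id),
                region=str(regions[0]),
                tract_ids=tuple(str(t) for t in sub["tract_id"]),
                brackets=tuple((lo, hi) for _, lo, hi in brackets),
                counts=sub[bcols].to_numpy(dtype=np.int64),
            )
        )
    return tables


def write_tract_tables(
    tables: Sequence[TractTable], path: str | Path, header_comment: str | None = None
) -> None:
    path = Path(path)
    frames = []
    for t in tables:
        cols = {
            "city_id": t.city_id,
            "region": t.region,
            "tract_id": list(t.tract_ids),
        }
        for k, (lo, hi) in enumerate(t.brackets):
            cols[bracket_label(lo, hi)] = t.counts[:, k]
        cols["total"] = t.totals
        frames.append(pd.DataFrame(cols))
    write_table(pd.concat(frames, ignore_index=True), path, header_comment)


def write_table(
    df: pd.DataFrame, path: str | Path, header_comment: str | None = None,
    index: bool = False,
) -> None:
    """Write a DataFrame as CSV, optionally preceded by a ``#`` comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a city-panel covariate table, validating required columns."""
    df = read_table(path)
    required = {"city_id", "region", "population", "gini", "gdp_pc",
                "unemployment", "poverty_rate", "sei"}
    missing = required - set(df.columns)
    if missing:
        raise SegregationError(f"{path}: panel missing columns {sorted(missing)}")
    return df
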
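"""Reading and writing calcium-trace tables and per-cell result tables.

The on-disk format is plain CSV: one column (or row) per cell, one row (or
column) per time point, an optional header of cell ids, and optional
``#``-prefixed provenance comment lines, which are always skipped on read.
Traces containing missing values are dropped with a warning, never imputed:
every downstream measure assumes a complete series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalciumTrace",
    "TraceSet",
    "read_traces",
    "write_traces",
    "write_results",
]

#: strings treated as missing values in input tables
_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none", "-"}

#: header labels recognised as a time/index column, dropped on read
_TIME_LABELS = {"t", "time", "frame", "index", "timepoint"}


@dataclass(frozen=True)
class CalciumTrace:
    """One cell's ordered fluorescence values.

    Parameters
    ----------
    cell_id : str
        Label of the cell (unique within a :class:`TraceSet`).
    values : numpy.ndarray
        Fluorescence values in acquisition order, arbitrary units. Must be
        finite and of length >= 2.
    sampling_rate_hz : float or None
        Sampling rate if known; purely metadata, no measure uses it.
    """

    cell_id: str
    values: np.ndarray
    sampling_rate_hz: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError(f"trace {self.cell_id!r}: values must be 1-D")
        if values.size < 2:
            raise ValueError(
                f"trace {self.cell_id!r}: need at least 2 time points, got {values.size}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"trace {self.cell_id!r}: non-finite values present")
        if self.sampling_rate_hz is not None and not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive or None")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class TraceSet:
    """A named population of traces (typically one experimental condition)."""

    name: str
    traces: list[CalciumTrace] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.cell_id for t in self.traces]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate cell_ids in TraceSet {self.name!r}: {dupes}")
        lengths = {len(t) for t in self.traces}
        if len(lengths) > 1:
            warnings.warn(
                f"TraceSet {self.name!r}: traces have differing lengths "
                f"{sorted(lengths)}; all measures are per-trace so this is "
                "allowed but may not be intended",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[CalciumTrace]:
        return iter(self.traces)

    def __getitem__(self, i: int) -> CalciumTrace:
        return self.traces[i]

    @property
    def cell_ids(self) -> list[str]:
        return [t.cell_id for t in self.traces]


def _is_numeric(token: str) -> bool:
    try:
        float(token)
    except (TypeError, ValueError):
        return False
    return True


def read_traces(
    path: str | Path,
    orientation: str = "time_rows",
    has_header: bool | None = None,
    name: str | None = None,
) -> TraceSet:
    """Read a CSV table of single-cell fluorescence time series.

    Parameters
    ----------
    path : path
        CSV file. ``#``-prefixed lines are treated as comments.
    orientation : {"time_rows", "time_columns"}
        ``time_rows`` (default): rows are time points, columns are cells —
        the typical imaging-software export. ``time_columns``: the transpose.
    has_header : bool or None
        Whether the file carries a row (resp. column) of cell ids. ``None``
        autodetects: any non-numeric, non-missing token in the first line
        (after orientation normalisation) is taken to mean ids are present.
    name : str, optional
        Name for the resulting :class:`TraceSet`; defaults to the file stem.

    Returns
    -------
    TraceSet
        One :class:`CalciumTrace` per cell. A leading column whose header is
        a time label (``t``, ``time``, ``frame``, ``index``) is dropped.
        Traces containing missing values are dropped with a warning.

    Raises
    ------
    ValueError
        On a non-numeric entry (the offending cell and position are named)
        or if no usable trace remains.
    """
    path = Path(path)
    if orientation not in ("time_rows", "time_columns"):
        raise ValueError(f"orientation must be time_rows|time_columns, got {orientation!r}")
    raw = pd.read_csv(
        path, header=None, comment="#", skip_blank_lines=True, dtype=str,
        keep_default_na=False,
    )
    if orientation == "time_columns":
        raw = raw.T.reset_index(drop=True)
        raw.columns = range(raw.shape[1])
    if raw.empty:
        raise ValueError(f"{path}: no data rows")

    first = [("" if v is None else str(v).strip()) for v in raw.iloc[0]]
    if has_header is None:
        has_header = any(
            tok.lower() not in _NA_TOKENS and not _is_numeric(tok) for tok in first
        )
    if has_header:
        ids = first
        body = raw.iloc[1:].reset_index(drop=True)
    else:
        ids = [f"cell_{j + 1:04d}" for j in range(raw.shape[1])]
        body = raw

    # drop a leading time/index column when the header names it as such
    start_col = 0
    if has_header and ids and ids[0].lower() in _TIME_LABELS:
        start_col = 1

    traces: list[CalciumTrace] = []
    for j in range(start_col, body.shape[1]):
        col = body.iloc[:, j]
        tokens = [("" if v is None else str(v).strip()) for v in col]
        vals = np.empty(len(tokens), dtype=float)
        missing = False
        for i, tok in enumerate(tokens):
            if tok.lower() in _NA_TOKENS:
                missing = True
                vals[i] = np.nan
            elif _is_numeric(tok):
                vals[i] = float(tok)
            else:
                raise ValueError(
                    f"{path}: non-numeric value {tok!r} for cell {ids[j]!r} "
                    f"at time point {i}"
                )
        if missing or not np.all(np.isfinite(vals)):
            warnings.warn(
                f"{path}: trace {ids[j]!r} contains missing values; dropped "
                "(policy: drop, never impute)",
                stacklevel=2,
            )
            continue
        traces.append(CalciumTrace(cell_id=ids[j], values=vals))
    if not traces:
        raise ValueError(f"{path}: no complete traces after applying the drop policy")
    return TraceSet(name=name if name is not None else path.stem, traces=traces)


def write_traces(
    traceset: TraceSet, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write a TraceSet as a time_rows CSV (columns = cells, header = ids)."""
    path = Path(path)
    lengths = {len(t) for t in traceset}
    if len(lengths) > 1:
        raise ValueError("cannot write a rectangular CSV from unequal-length traces")
    df = pd.DataFrame({t.cell_id: t.values for t in traceset})
    _write_csv(df, path, header_lines)


def write_results(
    table: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write a per-cell measure table (cell_id + one column per measure).

    Numeric columns are written with 17 significant digits so the table
    round-trips through :func:`pandas.read_csv` to better than 1e-12.
    """
    path = Path(path)
    if "cell_id" not in table.columns:
        raise ValueError("result table must have a 'cell_id' column")
    _write_csv(table, path, header_lines)


def _write_csv(df: pd.DataFrame, path: Path, header_lines: Iterable[str]) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a per-cell result table written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")
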
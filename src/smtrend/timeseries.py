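"""Time-series container and delimited-file ingestion.

A :class:`TimeSeries` is an ordered set of (time, value) pairs on a numeric
time axis — decimal years, nights, sample indices, whatever the caller uses.
Spacing may be regular (one observation per time unit, constant step) or
irregular (uneven steps and/or several observations per time unit, as in
monitoring data with many samples per year).  :func:`classify_spacing`
encodes that dichotomy, which downstream selects the interval-division
method.

Calendar parsing is deliberately out of scope: callers convert dates to
decimal numbers before ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyInputError,
    InsufficientDataError,
    ParseError,
)

__all__ = [
    "TimeSeries",
    "SpacingClass",
    "read_timeseries",
    "write_timeseries",
    "classify_spacing",
]

logger = logging.getLogger(__name__)

#: Relative tolerance under which consecutive time steps count as equal.
STEP_RTOL = 1e-9


@dataclass
class TimeSeries:
    """Ordered (time, value) observations.

    Construction sorts by time (stable, so ties keep input order) and rejects
    non-finite entries — dropping those is the reader's job, where they are
    counted.  ``n_dropped`` records how many rows the reader discarded.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    n_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D and of equal length")
        if t.size < 1:
            raise EmptyInputError("a TimeSeries needs at least one observation")
        if not (np.isfinite(t).all() and np.isfinite(v).all()):
            raise ValueError("times and values must be finite")
        order = np.argsort(t, kind="stable")
        self.times = t[order]
        self.values = v[order]

    @property
    def n(self) -> int:
        return self.times.size

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class SpacingClass:
    """Spacing verdict: ``kind`` is 'regular' or 'irregular'; ``step`` is the
    constant time step, defined only when regular."""

    kind: str
    step: Union[float, None] = None

    @property
    def is_regular(self) -> bool:
        return self.kind == "regular"


def _select_column(frame: pd.DataFrame, column: Union[str, int], role: str) -> pd.Series:
    if isinstance(column, (int, np.integer)):
        if not 0 <= int(column) < frame.shape[1]:
            raise ParseError(f"{role} column index {column} out of range "
                             f"for a file with {frame.shape[1]} columns")
        return frame.iloc[:, int(column)]
    if column not in frame.columns:
        raise ParseError(f"{role} column {column!r} not found; "
                         f"available: {list(frame.columns)}")
    return frame[column]


def _coerce_numeric(raw: pd.Series, role: str) -> pd.Series:
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = coerced.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric {role} value {raw.iloc[row]!r} at data row {row}"
        )
    return coerced


def read_timeseries(
    path,
    time_column: Union[str, int] = 0,
    value_column: Union[str, int] = 1,
    delimiter: str = ",",
    label: Union[str, None] = None,
) -> TimeSeries:
    """Read a two-column time series from a delimited text file.

    Columns are selected by header name or 0-based position.  Rows where
    either entry is missing or non-finite are dropped and counted
    (``result.n_dropped``); a cell that is present but not numeric raises
    :class:`~smtrend.exceptions.ParseError` naming the row.

    Parameters
    ----------
    path
        CSV/TSV file with a header row, UTF-8.
    time_column, value_column
        Header name (str) or 0-based column index (int).
    delimiter
        Field separator, e.g. ``","`` or ``"\\t"``.
    label
        Series label; defaults to the file stem.
    """
    try:
        frame = pd.read_csv(path, sep=delimiter, encoding="utf-8",
                            float_precision="round_trip")
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: no data rows") from exc
    t = _coerce_numeric(_select_column(frame, time_column, "time"), "time")
    v = _coerce_numeric(_select_column(frame, value_column, "value"), "value")
    keep = np.isfinite(t.to_numpy(dtype=float)) & np.isfinite(v.to_numpy(dtype=float))
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise EmptyInputError(f"{path}: zero parseable rows")
    if n_dropped:
        logger.info("read_timeseries: dropped %d row(s) with missing/non-finite "
                    "entries from %s", n_dropped, path)
    if label is None:
        label = getattr(path, "stem", None) or str(path)
    return TimeSeries(
        times=t.to_numpy(dtype=float)[keep],
        values=v.to_numpy(dtype=float)[keep],
        label=str(label),
        n_dropped=n_dropped,
    )


def write_timeseries(
    ts: TimeSeries,
    path,
    delimiter: str = ",",
    time_column: str = "time",
    value_column: str = "value",
) -> None:
    """Write a series as a two-column delimited file with header.

    Floats are written in shortest round-trip notation, so
    read(write(ts)) reproduces times and values bit-identically.
    """
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"{time_column}{delimiter}{value_column}\n")
        for t, v in zip(ts.times, ts.values):
            handle.write(f"{float(t)!r}{delimiter}{float(v)!r}\n")


def classify_spacing(ts: TimeSeries, rtol: float = STEP_RTOL) -> SpacingClass:
    """Classify a series as regularly or irregularly spaced.

    Regular means exactly one observation per time point and all consecutive
    steps equal within relative tolerance ``rtol``; anything else (uneven
    steps, duplicate times) is irregular.  The verdict is invariant under
    affine rescaling of the time axis.
    """
    if ts.n < 2:
        raise InsufficientDataError(
            "spacing classification needs at least 2 observations"
        )
    diffs = np.diff(ts.times)
    step = float(diffs.mean())
    if np.any(diffs <= 0):
        return SpacingClass("irregular")
    if np.all(np.abs(diffs - step) <= rtol * abs(step)):
        return SpacingClass("regular", step=step)
    return SpacingClass("irregular")
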
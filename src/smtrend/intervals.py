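"""Interval division of a time series and interval mean values.

Two division methods are provided, one per spacing class:

* **equal time steps** — for regular series with one observation per time
  unit.  Observation *i* (0-based) is modelled as a unit cell ``[i, i+1)``
  on an axis of length *n*; that axis is cut into *k* equal cells of length
  ``n/k`` and each observation contributes to an interval with weight equal
  to the overlap of its unit cell with the interval's cell.  The interval
  mean is the weight-weighted mean, i.e. ``sum(w_ij * y_i) / (n/k)``.
  For n=7, k=3 this yields the weights (1, 1, 1/3) / (2 + 1/3) for the
  first interval, (2/3, 1, 2/3) for the second and (1/3, 1, 1) for the
  third.  Every weight is an exact multiple of ``1/k``; the implementation
  therefore works in integer arithmetic (numerators over denominator *k*)
  and is exact.

* **different time steps** — for irregular series.  The time range is cut
  into *k* equal-length sub-ranges, half-open on the right except the last;
  each observation falls wholly in the sub-range containing its time and
  the interval mean is the unweighted mean of its values.  When every time
  coordinate is an integer the range is treated as inclusive unit blocks,
  i.e. ``[t_min, t_max + 1)``, so that times 1..9 split into thirds as
  1–3, 4–6, 7–9.

Both methods produce strictly increasing, equally spaced interval
midpoints, so any subsequent regression statistic that is invariant under
affine maps of the predictor (r-squared, t, p) does not depend on whether
midpoints or interval indices are regressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .exceptions import (
    InvalidDivisionError,
    MethodMismatchError,
    SeriesTooShortError,
)
from .timeseries import TimeSeries, classify_spacing

__all__ = [
    "IntervalMeans",
    "equal_steps_weight_numerators",
    "divide_equal_time_steps",
    "divide_different_time_steps",
    "max_divisions",
    "MIN_INTERVALS",
]

#: Smallest usable interval count: k - 2 regression degrees of freedom >= 1.
MIN_INTERVALS = 3


@dataclass
class IntervalMeans:
    """The result of one k-interval division.

    Attributes
    ----------
    k : int
        Number of intervals.
    midpoints : ndarray
        Representative time coordinate of each interval (its centre on the
        time axis); strictly increasing and equally spaced.
    means : ndarray
        Interval mean values; NaN where an interval is empty.
    support : ndarray
        Total weight per interval: ``n/k`` for the equal-steps method,
        the observation count for the different-steps method.
    method : str
        ``"equal_time_steps"`` or ``"different_time_steps"``.
    empty_intervals : int
        Number of intervals with zero support.  Non-zero marks the division
        unusable for regression; callers skip it.
    """

    k: int
    midpoints: np.ndarray
    means: np.ndarray
    support: np.ndarray
    method: str
    empty_intervals: int = 0

    @property
    def usable(self) -> bool:
        return self.empty_intervals == 0


def equal_steps_weight_numerators(n: int, k: int) -> np.ndarray:
    """Integer weight numerators for the equal-time-steps division.

    Returns a ``(k, n)`` integer array ``o`` such that observation *i*'s
    weight in interval *j* is exactly ``o[j, i] / k`` and the interval mean
    is exactly ``(o[j] @ y) / n``.  Rows sum to *n* (each interval holds
    ``n/k`` units of weight, i.e. support ``n/k``), columns sum to *k*
    (each observation's weights sum to 1): observation mass is conserved
    exactly, with no floating-point involvement.
    """
    if not (MIN_INTERVALS <= k <= n):
        raise InvalidDivisionError(f"k must satisfy {MIN_INTERVALS} <= k <= n={n}; got {k}")
    i = np.arange(n, dtype=np.int64)
    j = np.arange(k, dtype=np.int64)[:, None]
    # Unit cell of obs i scaled by k: [i*k, (i+1)*k); interval j scaled by k:
    # [j*n, (j+1)*n).  Overlap lengths are integers on this common grid.
    lo = np.maximum(i * k, j * n)
    hi = np.minimum((i + 1) * k, (j + 1) * n)
    return np.clip(hi - lo, 0, None)


def divide_equal_time_steps(ts: TimeSeries, k: int) -> IntervalMeans:
    """Divide a regular series into k intervals by unit-cell overlap weights.

    Requires a regularly spaced series (one observation per time unit) and
    ``3 <= k <= n``.  Never produces empty intervals.
    """
    spacing = classify_spacing(ts)
    if not spacing.is_regular:
        raise MethodMismatchError(
            "equal-time-steps division requires a regularly spaced series; "
            "use divide_different_time_steps"
        )
    n = ts.n
    numer = equal_steps_weight_numerators(n, k)
    means = numer @ ts.values / n
    step = spacing.step
    # Interval centres on the time axis: unit cell i covers
    # [t_i - step/2, t_i + step/2), so the axis origin is t_0 - step/2.
    origin = ts.times[0] - step / 2.0
    midpoints = origin + step * (np.arange(k) + 0.5) * (n / k)
    support = np.full(k, n / k)
    return IntervalMeans(
        k=k,
        midpoints=midpoints,
        means=means,
        support=support,
        method="equal_time_steps",
        empty_intervals=0,
    )


def divide_different_time_steps(
    ts: TimeSeries,
    k: int,
    integer_blocks: Union[bool, str] = "auto",
) -> IntervalMeans:
    """Divide an arbitrarily spaced series into k equal time sub-ranges.

    The time range is split into k equal-length sub-ranges, right-half-open
    except the last (closed), and each observation is assigned wholly to the
    sub-range containing its time.  With ``integer_blocks`` true (the
    default resolves to true when all times are integers) the range is
    ``[t_min, t_max + 1)``, reading integer times as inclusive unit blocks.

    An empty sub-range does not raise: the division is returned with
    ``empty_intervals > 0`` (means NaN there) and callers skip it.
    """
    n = ts.n
    if not (MIN_INTERVALS <= k <= n):
        raise InvalidDivisionError(f"k must satisfy {MIN_INTERVALS} <= k <= n={n}; got {k}")
    if integer_blocks == "auto":
        integer_blocks = bool(np.all(ts.times == np.floor(ts.times)))
    lo = ts.times[0]
    hi = ts.times[-1] + (1.0 if integer_blocks else 0.0)
    if hi <= lo:
        raise InvalidDivisionError("time range has zero extent")
    edges = np.linspace(lo, hi, k + 1)
    idx = np.clip(np.searchsorted(edges, ts.times, side="right") - 1, 0, k - 1)
    counts = np.bincount(idx, minlength=k)
    sums = np.bincount(idx, weights=ts.values, minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    midpoints = 0.5 * (edges[:-1] + edges[1:])
    return IntervalMeans(
        k=k,
        midpoints=midpoints,
        means=means,
        support=counts.astype(float),
        method="different_time_steps",
        empty_intervals=int((counts == 0).sum()),
    )


def max_divisions(
    ts: TimeSeries,
    method: str,
    cap: int = 30,
    integer_blocks: Union[bool, str] = "auto",
) -> int:
    """Largest usable interval count not exceeding ``cap``.

    For the equal-steps method this is ``min(cap, n)``.  For the
    different-steps method, interval counts are scanned downward from
    ``min(cap, n)`` and the first k with no empty sub-range is returned.
    Raises :class:`~smtrend.exceptions.SeriesTooShortError` when no
    k >= 3 is usable.
    """
    upper = min(cap, ts.n)
    if upper < MIN_INTERVALS:
        raise SeriesTooShortError(
            f"series of length {ts.n} cannot be divided into {MIN_INTERVALS} intervals"
        )
    if method == "equal_time_steps":
        return upper
    if method != "different_time_steps":
        raise ValueError(f"unknown method {method!r}")
    for k in range(upper, MIN_INTERVALS - 1, -1):
        if divide_different_time_steps(ts, k, integer_blocks).usable:
            return k
    raise SeriesTooShortError(
        f"no interval count in [{MIN_INTERVALS}, {upper}] divides the series "
        "without empty intervals"
    )
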
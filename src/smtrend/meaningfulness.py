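"""The statistical-meaningfulness test for linear time trends.

Statistical significance of a linear trend is cheap when n is large: a
monitoring series with tens of thousands of samples can put p far below
0.001 while its points scatter so widely that r-squared is near zero.  The
meaningfulness test adds a predictive-power requirement.  A series is
declared *statistically meaningful* when the regression of time against
the raw values, **or** against the interval means of any division of the
series into k = 3..k_max consecutive intervals, reaches both
r2 >= r2_min (default 0.65) and p <= p_max (default 0.05), comparisons
inclusive.

Aggregating into few interval means strips high-frequency scatter, so a
genuine monotone drift can clear the r2 bar at small k even when the
full-series r2 is low; pure scatter cannot, because few means also mean
few degrees of freedom and hence a demanding critical r2.

No multiple-testing correction is applied across the k sweep: the verdict
is an intentionally liberal disjunction over divisions, and per-division
statistics are reported so users can judge for themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .exceptions import InsufficientDataError
from .intervals import (
    MIN_INTERVALS,
    IntervalMeans,
    divide_different_time_steps,
    divide_equal_time_steps,
)
from .regression import RegressionResult, linear_regression
from .timeseries import TimeSeries, classify_spacing

__all__ = [
    "Thresholds",
    "DivisionOutcome",
    "MeaningfulnessResult",
    "test_meaningfulness",
    "sensitivity_analysis",
    "redundancy_scan",
]


@dataclass(frozen=True)
class Thresholds:
    """Verdict thresholds and the division-count sweep range.

    Defaults are the published operating point: r2 >= 0.65 (Prairie's
    predictive-power threshold), p <= 0.05, divisions swept over 3..30.
    Sweeping past 30 is valid but adds little: interval means from large
    division counts almost never out-perform those from small ones.
    """

    r2_min: float = 0.65
    p_max: float = 0.05
    k_min: int = MIN_INTERVALS
    k_max: int = 30

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_min < 1.0:
            raise ValueError(f"r2_min must lie in (0, 1); got {self.r2_min}")
        if not 0.0 < self.p_max < 1.0:
            raise ValueError(f"p_max must lie in (0, 1); got {self.p_max}")
        if not MIN_INTERVALS <= self.k_min <= self.k_max:
            raise ValueError(
                f"need {MIN_INTERVALS} <= k_min <= k_max; got "
                f"k_min={self.k_min}, k_max={self.k_max}"
            )

    def qualifies(self, reg: RegressionResult) -> bool:
        """Inclusive dual-threshold check on one regression."""
        return reg.r_squared >= self.r2_min and reg.p_value <= self.p_max


@dataclass(frozen=True)
class DivisionOutcome:
    """One division count's contribution: a regression, or a skip reason."""

    k: int
    regression: Optional[RegressionResult] = None
    skipped_reason: Optional[str] = None

    @property
    def skipped(self) -> bool:
        return self.regression is None


@dataclass
class MeaningfulnessResult:
    """Full output of one meaningfulness test."""

    label: str
    full_series: RegressionResult
    per_division: Dict[int, DivisionOutcome]
    qualifying_divisions: List[int]
    full_series_qualifies: bool
    verdict: str
    thresholds: Thresholds
    method: str
    divisions: Dict[int, IntervalMeans] = field(default_factory=dict, repr=False)

    @property
    def meaningful(self) -> bool:
        return self.verdict == "meaningful"


def _verdict(full_qualifies: bool, qualifying: Sequence[int]) -> str:
    return "meaningful" if (full_qualifies or len(qualifying) > 0) else "not_meaningful"


def test_meaningfulness(
    ts: TimeSeries,
    thresholds: Optional[Thresholds] = None,
    method: str = "auto",
    integer_blocks: Union[bool, str] = "auto",
    keep_divisions: bool = False,
) -> MeaningfulnessResult:
    """Run the statistical-meaningfulness test on one time series.

    Regresses time against the raw values, then against the interval means
    of every division into k = k_min .. min(k_max, n) intervals, and
    declares the trend meaningful when any of those regressions meets both
    thresholds (inclusive).

    Parameters
    ----------
    ts
        The series under test, n >= 3.
    thresholds
        Verdict thresholds; defaults to ``Thresholds()`` (0.65 / 0.05, 3..30).
    method
        ``"auto"`` selects equal-time-steps for regularly spaced series and
        different-time-steps otherwise; ``"equal"`` / ``"different"`` force
        one method.
    integer_blocks
        Passed to the different-steps division: treat integer time units as
        inclusive unit blocks (range extended to t_max + 1).
    keep_divisions
        If true, the :class:`~smtrend.intervals.IntervalMeans` for each
        evaluated k are retained on the result for inspection/export.

    Notes
    -----
    Divisions with empty intervals (possible only under the different-steps
    method, when a sub-range contains no observation) are recorded as
    skipped, with reason, and do not block the rest of the sweep.
    """
    thr = thresholds if thresholds is not None else Thresholds()
    if ts.n < 3:
        raise InsufficientDataError(f"meaningfulness test needs n >= 3; got {ts.n}")
    if method == "auto":
        resolved = "equal" if classify_spacing(ts).is_regular else "different"
    elif method in ("equal", "different"):
        resolved = method
    else:
        raise ValueError(f"method must be auto|equal|different; got {method!r}")

    full = linear_regression(ts.times, ts.values)

    upper = min(thr.k_max, ts.n)
    if upper < thr.k_min:
        raise InsufficientDataError(
            f"series of length {ts.n} cannot be divided into k_min={thr.k_min} intervals"
        )

    per_division: Dict[int, DivisionOutcome] = {}
    divisions: Dict[int, IntervalMeans] = {}
    qualifying: List[int] = []
    for k in range(thr.k_min, upper + 1):
        if resolved == "equal":
            im = divide_equal_time_steps(ts, k)
        else:
            im = divide_different_time_steps(ts, k, integer_blocks=integer_blocks)
        if keep_divisions:
            divisions[k] = im
        if not im.usable:
            per_division[k] = DivisionOutcome(
                k=k,
                skipped_reason=f"{im.empty_intervals} empty interval(s)",
            )
            continue
        reg = linear_regression(im.midpoints, im.means)
        per_division[k] = DivisionOutcome(k=k, regression=reg)
        if thr.qualifies(reg):
            qualifying.append(k)

    full_q = thr.qualifies(full)
    method_name = "equal_time_steps" if resolved == "equal" else "different_time_steps"
    return MeaningfulnessResult(
        label=ts.label,
        full_series=full,
        per_division=per_division,
        qualifying_divisions=qualifying,
        full_series_qualifies=full_q,
        verdict=_verdict(full_q, qualifying),
        thresholds=thr,
        method=method_name,
        divisions=divisions,
    )


def _verdict_at(result: MeaningfulnessResult, r2_min: float, p_max: float) -> bool:
    """Re-evaluate a computed result's verdict under different limits."""
    regs = [result.full_series] + [
        d.regression for d in result.per_division.values() if not d.skipped
    ]
    return any(r.r_squared >= r2_min and r.p_value <= p_max for r in regs)


def sensitivity_analysis(
    series_set: Iterable[TimeSeries],
    r2_grid: Sequence[float],
    p_grid: Sequence[float],
    thresholds: Optional[Thresholds] = None,
    method: str = "auto",
) -> Dict[Tuple[float, float], List[str]]:
    """Which series stay meaningful as the (p, r2) limits move.

    Runs the test once per series (the per-division regressions do not
    depend on the limits) and re-applies every ``(p_limit, r2_limit)`` pair
    from the grids.  Returns a mapping ``(p_limit, r2_limit) -> sorted list
    of series labels declared meaningful`` — one row per limit pair, the
    layout of a sensitivity table.

    Because the qualification comparisons are inclusive and monotone in the
    limits, the returned sets are nested: relaxing either limit can only
    grow the meaningful set.
    """
    if not r2_grid or not p_grid:
        raise ValueError("r2_grid and p_grid must be non-empty")
    for g, name in ((r2_grid, "r2_grid"), (p_grid, "p_grid")):
        if any(not 0.0 < v < 1.0 for v in g):
            raise ValueError(f"{name} values must lie in (0, 1)")
    results = [
        test_meaningfulness(ts, thresholds=thresholds, method=method)
        for ts in series_set
    ]
    table: Dict[Tuple[float, float], List[str]] = {}
    for p_limit in p_grid:
        for r2_limit in r2_grid:
            table[(p_limit, r2_limit)] = sorted(
                res.label for res in results if _verdict_at(res, r2_limit, p_limit)
            )
    return table


def redundancy_scan(result: MeaningfulnessResult, k_limit: int = 19) -> bool:
    """Would capping the division sweep at ``k_limit`` change the verdict?

    Returns True when restricting the qualifying divisions to k <= k_limit
    leaves the verdict unchanged — i.e. divisions above ``k_limit`` were
    redundant for this series.  Vacuously true for a not-meaningful result.
    """
    if k_limit < result.thresholds.k_min:
        raise ValueError(
            f"k_limit must be >= k_min={result.thresholds.k_min}; got {k_limit}"
        )
    restricted = result.full_series_qualifies or any(
        k <= k_limit for k in result.qualifying_divisions
    )
    return _verdict(restricted, []) == result.verdict
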
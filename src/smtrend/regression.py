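"""Bivariate linear-regression statistics for trend testing.

The statistics are the classical ones: r-squared is the squared Pearson
correlation between time and value, the t statistic follows from n and
r-squared alone,

    t = sqrt(r2 * (n - 2) / (1 - r2)),

and the two-tailed p-value comes from Student's t distribution with
n - 2 degrees of freedom.  t is reported as a magnitude; the direction of
the trend is carried separately in ``slope_sign``.

A response with zero variance is flagged degenerate and assigned r2 = 0,
p = 1: a flat series is the canonical "no trend" and must never pass a
threshold test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientDataError, InvalidPredictorError

__all__ = [
    "RegressionResult",
    "linear_regression",
    "t_from_r2",
    "p_from_t",
    "critical_r2",
]

# Smallest positive double: p-values are clamped here so that p stays in
# (0, 1] even for an exactly collinear input (t = inf).
_P_FLOOR = 5e-324


@dataclass(frozen=True)
class RegressionResult:
    """Statistics of one time-versus-values ordinary least squares fit."""

    n: int
    slope: float
    intercept: float
    r_squared: float
    t_value: float
    df: int
    p_value: float
    slope_sign: str
    degenerate: bool = False


def _sign(slope: float) -> str:
    if slope > 0:
        return "positive"
    if slope < 0:
        return "negative"
    return "zero"


def linear_regression(x, y) -> RegressionResult:
    """OLS fit of y on x with r2, t and two-tailed p at df = n - 2.

    Requires n >= 3 equal-length sequences and non-constant x.  Constant y
    is handled by the degenerate convention (r2 = 0, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"regression needs n >= 3 pairs; got {n}")
    if np.ptp(x) == 0:
        raise InvalidPredictorError("predictor (time) axis has zero variance")
    df = n - 2
    if np.ptp(y) == 0:
        return RegressionResult(
            n=n, slope=0.0, intercept=float(y[0]), r_squared=0.0,
            t_value=0.0, df=df, p_value=1.0, slope_sign="zero",
            degenerate=True,
        )
    fit = sps.linregress(x, y)
    r2 = min(float(fit.rvalue) ** 2, 1.0)
    t = t_from_r2(r2, n)
    p = p_from_t(t, df) if math.isfinite(t) else _P_FLOOR
    return RegressionResult(
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        t_value=t,
        df=df,
        p_value=p,
        slope_sign=_sign(float(fit.slope)),
    )


def t_from_r2(r_squared: float, n: int) -> float:
    """Magnitude of the regression t statistic from n and r-squared.

    Returns ``inf`` for r_squared exactly 1 (perfectly collinear data).
    """
    if n < 3:
        raise InsufficientDataError(f"t statistic needs n >= 3; got {n}")
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError(f"r_squared must lie in [0, 1]; got {r_squared}")
    if r_squared == 1.0:
        return math.inf
    return math.sqrt(r_squared * (n - 2) / (1.0 - r_squared))


def p_from_t(t_value: float, df: int) -> float:
    """Two-tailed Student-t tail probability, clamped into (0, 1]."""
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1; got {df}")
    if not math.isfinite(t_value):
        return _P_FLOOR
    p = 2.0 * float(sps.t.sf(abs(t_value), df))
    return min(max(p, _P_FLOOR), 1.0)


def critical_r2(n: int, p_limit: float = 0.05) -> float:
    """The r-squared at which the two-tailed p equals ``p_limit`` for n pairs.

    Inverts the t statistic at the critical two-tailed t with df = n - 2:
    ``r2_crit = t_c**2 / (t_c**2 + n - 2)``.  Any fit of n pairs with
    r-squared at or above this value is significant at ``p_limit``.
    """
    if n < 3:
        raise InsufficientDataError(f"critical r2 needs n >= 3; got {n}")
    if not 0.0 < p_limit < 1.0:
        raise ValueError(f"p_limit must lie in (0, 1); got {p_limit}")
    df = n - 2
    t_c = float(sps.t.ppf(1.0 - p_limit / 2.0, df))
    return t_c * t_c / (t_c * t_c + df)
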
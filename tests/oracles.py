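"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's computation paths: r-squared is a
direct transcription of the defining sum formula, the two-tailed p comes
from numeric integration of a hand-written Student-t density, and interval
means are recomputed with exact rational arithmetic from the overlap
definition.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.integrate import quad


def r2_direct(x, y) -> float:
    """Coefficient of determination, straight from the defining sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x.mean()
    ym = y.mean()
    num = float(np.sum((x - xm) * (y - ym))) ** 2
    den = float(np.sum((x - xm) ** 2)) * float(np.sum((y - ym) ** 2))
    return num / den


def slope_direct(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2))


def t_density(u: float, df: int) -> float:
    """Student-t probability density, written out with gamma functions."""
    c = math.exp(math.lgamma((df + 1) / 2.0) - math.lgamma(df / 2.0))
    c /= math.sqrt(df * math.pi)
    return c * (1.0 + u * u / df) ** (-(df + 1) / 2.0)


def p_twotailed_quad(t_value: float, df: int) -> float:
    """Two-tailed tail probability by numeric integration of the density."""
    tail, _ = quad(t_density, abs(t_value), np.inf, args=(df,))
    return min(2.0 * tail, 1.0)


def t_from_r2_formula(r2: float, n: int) -> float:
    return math.sqrt(r2 * (n - 2) / (1.0 - r2))


def critical_r2_bisect(n: int, p_limit: float, tol: float = 1e-12) -> float:
    """Invert p(r2) = p_limit by bisection on the quad-integration p."""
    lo, hi = 0.0, 1.0 - 1e-15
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        p = p_twotailed_quad(t_from_r2_formula(mid, n), n - 2)
        if p > p_limit:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def equal_steps_means_fraction(y, k: int):
    """Interval means by exact rational overlap weighting.

    Observation i occupies [i, i+1) on an axis of length n; interval j is
    [j*n/k, (j+1)*n/k).  Returns a list of Fractions when y is integral,
    otherwise floats assembled from exact rational weights.
    """
    n = len(y)
    means = []
    for j in range(k):
        lo_j = Fraction(j * n, k)
        hi_j = Fraction((j + 1) * n, k)
        total = Fraction(0)
        for i, yi in enumerate(y):
            w = max(Fraction(0), min(Fraction(i + 1), hi_j) - max(Fraction(i), lo_j))
            total += w * (Fraction(yi) if isinstance(yi, int) else Fraction(float(yi)))
        means.append(total / Fraction(n, k))
    return means


def different_steps_means_manual(times, values, k: int, lo: float, hi: float):
    """Unweighted means over k equal sub-ranges of [lo, hi), last closed."""
    width = (hi - lo) / k
    buckets = [[] for _ in range(k)]
    for t, v in zip(times, values):
        j = min(int((t - lo) / width), k - 1)
        buckets[j].append(v)
    return [sum(b) / len(b) if b else math.nan for b in buckets]
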
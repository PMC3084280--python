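"""Monte Carlo characterisation experiments for the meaningfulness test.

Each experiment draws many synthetic series from a registered generator
form, divides every series into each interval count in a sweep (default
3..25) with the equal-time-steps method, regresses interval midpoints
against interval means, and aggregates the per-division r-squared and
p statistics:

* :func:`division_frequency_experiment` — how often each division count's
  means pass the thresholds, each k tallied independently of the others.
* :func:`k_landscape_experiment` — the per-run, per-k (r2, p) landscape
  and the median r2 per k: small division counts yield systematically
  higher r-squared.
* :func:`k6_dominance_experiment` — how often the 6-interval division's
  r-squared exceeds that of each of the 20..25-interval divisions, and by
  how much it falls short when it does not.
* :func:`redundancy_fraction` — how often capping the sweep at k <= 19
  leaves the per-run verdict unchanged.
* :func:`breakpoint_table` — no sampling: the analytic critical r-squared
  per number of data pairs, locating the count (7) at which the p <= 0.05
  requirement stops binding once r2 >= 0.65 holds.

Experiments are seed-deterministic: per-run seeds are derived from the
spec's seed with a seed sequence, so run j of a given spec is always the
same series.  Published-scale settings (100,000 runs of length-1000
series) run through the identical code path as the reduced default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .generators import GeneratorSpec, generate_eq3_series
from .intervals import equal_steps_weight_numerators
from .meaningfulness import Thresholds
from .regression import critical_r2, linear_regression

__all__ = [
    "SimulationRecord",
    "DominanceResult",
    "simulate_records",
    "division_frequency_experiment",
    "k_landscape_experiment",
    "k6_dominance_experiment",
    "redundancy_fraction",
    "breakpoint_table",
    "DEFAULT_SWEEP",
]

#: Default division-count sweep for the sampling experiments.
DEFAULT_SWEEP = tuple(range(3, 26))


@dataclass(frozen=True)
class SimulationRecord:
    """One Monte Carlo run: per-division (r2, p) and the qualifying set."""

    run_id: int
    per_k: Dict[int, Tuple[float, float]]
    qualifying_k: frozenset


def _run_seeds(seed: int, runs: int) -> np.ndarray:
    """Derive one sub-seed per run, reproducibly, each below 2**31."""
    state = np.random.SeedSequence(seed).generate_state(runs, dtype=np.uint32)
    return (state & 0x7FFFFFFF).astype(np.int64)


def simulate_records(
    spec: GeneratorSpec,
    runs: int,
    thresholds: Optional[Thresholds] = None,
    sweep: Sequence[int] = DEFAULT_SWEEP,
) -> List[SimulationRecord]:
    """Generate ``runs`` series and evaluate every division count in ``sweep``.

    Series come from :func:`~smtrend.generators.generate_eq3_series` with
    per-run derived seeds; divisions use the equal-time-steps weights
    (generated series are regular with step 1) and the regression of
    interval midpoints on interval means.
    """
    if runs < 1:
        raise ValueError(f"runs must be >= 1; got {runs}")
    thr = thresholds if thresholds is not None else Thresholds()
    ks = sorted(set(int(k) for k in sweep))
    if ks and (ks[0] < 3 or ks[-1] > spec.n):
        raise ValueError(f"sweep must lie within [3, n={spec.n}]; got {ks[0]}..{ks[-1]}")
    # Division weights depend only on (n, k): build once, reuse per run.
    numerators = {k: equal_steps_weight_numerators(spec.n, k) for k in ks}
    midpoints = {k: (np.arange(k) + 0.5) * (spec.n / k) + 0.5 for k in ks}
    records: List[SimulationRecord] = []
    for run_id, sub_seed in enumerate(_run_seeds(spec.seed, runs)):
        series = generate_eq3_series(replace(spec, seed=int(sub_seed)))
        per_k: Dict[int, Tuple[float, float]] = {}
        qualifying = []
        for k in ks:
            means = numerators[k] @ series.values / spec.n
            reg = linear_regression(midpoints[k], means)
            per_k[k] = (reg.r_squared, reg.p_value)
            if thr.qualifies(reg):
                qualifying.append(k)
        records.append(
            SimulationRecord(run_id=run_id, per_k=per_k, qualifying_k=frozenset(qualifying))
        )
    return records


def division_frequency_experiment(
    spec: GeneratorSpec,
    runs: int,
    thresholds: Optional[Thresholds] = None,
    sweep: Sequence[int] = DEFAULT_SWEEP,
    tally: str = "per_division",
    records: Optional[List[SimulationRecord]] = None,
) -> Dict[int, int]:
    """Count, per division count k, the runs whose k-interval means qualify.

    With ``tally="per_division"`` (default) every qualifying k of a run is
    counted, regardless of whether other division counts of the same run
    also qualified.  With ``tally="once_per_run"`` each run credits only
    its best-qualifying k (highest r-squared among qualifiers).
    """
    if tally not in ("per_division", "once_per_run"):
        raise ValueError(f"tally must be per_division|once_per_run; got {tally!r}")
    if records is None:
        records = simulate_records(spec, runs, thresholds, sweep)
    ks = sorted(records[0].per_k) if records else sorted(set(sweep))
    counts = {k: 0 for k in ks}
    for rec in records:
        if tally == "per_division":
            for k in rec.qualifying_k:
                counts[k] += 1
        elif rec.qualifying_k:
            best = max(rec.qualifying_k, key=lambda k: rec.per_k[k][0])
            counts[best] += 1
    return counts


def k_landscape_experiment(
    spec: GeneratorSpec,
    runs: int,
    sweep: Sequence[int] = DEFAULT_SWEEP,
    records: Optional[List[SimulationRecord]] = None,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-run per-k (r2, p) scatter table plus the median r2 per k.

    Returns ``(table, median_r2)`` where ``table`` has columns
    ``run, k, r2, p`` (one row per run per division count) and
    ``median_r2`` is indexed by k.
    """
    if records is None:
        records = simulate_records(spec, runs, sweep=sweep)
    rows = [
        (rec.run_id, k, r2, p)
        for rec in records
        for k, (r2, p) in sorted(rec.per_k.items())
    ]
    table = pd.DataFrame(rows, columns=["run", "k", "r2", "p"])
    median_r2 = table.groupby("k")["r2"].median()
    return table, median_r2


@dataclass(frozen=True)
class DominanceResult:
    """Outcome of the 6-interval versus 20..25-interval r-squared comparison."""

    fraction_exceeding: float
    max_shortfall: float
    comparisons: int


def k6_dominance_experiment(
    spec: GeneratorSpec,
    runs: int,
    compare: Sequence[int] = tuple(range(20, 26)),
    records: Optional[List[SimulationRecord]] = None,
) -> DominanceResult:
    """How often does the 6-interval division out-correlate 20..25 intervals?

    For every run and every k' in ``compare``, tests r2(6) > r2(k')
    (strictly; exact ties, as on a noise-free line, do not count as
    exceeding).  Reports the exceedance fraction and, over the comparisons
    not exceeded, the largest shortfall r2(k') - r2(6).
    """
    ks = sorted(set([6, *compare]))
    if records is None:
        records = simulate_records(spec, runs, sweep=ks)
    exceed = 0
    total = 0
    shortfall = 0.0
    for rec in records:
        r2_6 = rec.per_k[6][0]
        for kp in compare:
            r2_p = rec.per_k[kp][0]
            total += 1
            if r2_6 > r2_p:
                exceed += 1
            else:
                shortfall = max(shortfall, r2_p - r2_6)
    return DominanceResult(
        fraction_exceeding=exceed / total if total else 0.0,
        max_shortfall=shortfall,
        comparisons=total,
    )


def redundancy_fraction(
    records: Iterable[SimulationRecord],
    k_limit: int = 19,
) -> float:
    """Fraction of runs whose verdict survives capping the sweep at k_limit.

    A run's division-based verdict is "some k qualifies"; the function
    reports how often that verdict is identical when only k <= k_limit are
    admitted.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    same = sum(
        (len(rec.qualifying_k) > 0) == any(k <= k_limit for k in rec.qualifying_k)
        for rec in records
    )
    return same / len(records)


def breakpoint_table(
    n_range: Sequence[int],
    p_limit: float = 0.05,
    r2_limit: float = 0.65,
) -> pd.DataFrame:
    """Analytic critical r-squared per number of data pairs.

    For each n, computes the r2 at which the two-tailed p equals
    ``p_limit`` (df = n - 2) and flags whether reaching ``r2_limit``
    alone already guarantees significance (critical r2 <= r2_limit).
    With the default limits the flag turns on at n = 7: from seven data
    pairs upwards, r2 = 0.65 implies p <= 0.05, while for 3..6 pairs an
    r2 above 0.65 can still be non-significant.
    """
    rows = [
        (int(n), critical_r2(int(n), p_limit), critical_r2(int(n), p_limit) <= r2_limit)
        for n in n_range
    ]
    return pd.DataFrame(rows, columns=["n", "critical_r2", "r2_limit_sufficient"])
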
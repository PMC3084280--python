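# smtrend

**Statistical meaningfulness testing for linear time trends.**

Statistical significance is a weak quality bar for trends in long series:
with tens of thousands of observations, a monitoring variable can show a
trend with p < 0.001 whose points scatter so far from the line that
r² ≈ 0.003 — significant, but useless for prediction or management.
`smtrend` implements a stricter, operational criterion aimed at
environmental monitoring, climatology, epidemiology and any field that
screens time series before deeper analysis:

> A time trend is **statistically meaningful** if the regression of time
> against the series values, *or* against the interval mean values of some
> division of the series into k = 3..30 consecutive intervals, reaches
> **r² ≥ 0.65** at **p ≤ 0.05**.

Here r² is the squared Pearson correlation between time and value,
the t statistic follows from n and r² alone,

    t = sqrt( r² (n − 2) / (1 − r²) ),        df = n − 2,

and p is the two-tailed Student-t tail probability. The r² bar of 0.65 is
the classical predictive-power threshold for bivariate regressions; the
0.05 level is the conventional significance bar. Averaging a series into
a few interval means strips high-frequency scatter, so a genuine monotone
drift can clear the r² bar at small k even when the full-series r² is
low — while pure scatter cannot, because few means also mean few degrees
of freedom and hence a demanding critical r².

Two interval-division methods cover the two spacing regimes:

* **equal time steps** (regular series, one value per time unit):
  observations are fractionally weighted by the overlap of their unit time
  cell with each of k equal cells — for 7 points in 3 intervals the first
  mean is (y₁ + y₂ + ⅓·y₃)/(2 + ⅓). Weights are computed in exact integer
  arithmetic.
* **different time steps** (uneven spacing, several samples per time
  unit): the time range is cut into k equal sub-ranges and values are
  averaged within each.

The package also ships the Monte Carlo harness used to characterise the
test (division-count qualification frequencies, the 6-versus-20..25
interval r² comparison, the redundancy of divisions beyond 19, and the
analytic n–p–r² breakpoint table).

## Worked example

```python
import smtrend as st

ts = st.generate_trend_noise(n=100, slope=1.0, noise_sd=44.0, seed=2)
result = st.test_meaningfulness(ts)
```

Running `python examples/test_a_trend.py` prints:

```
full-series fit:      r2 = 0.280, p = 1.6e-08 (positive slope)
division method:      equal_time_steps
qualifying divisions: [4, 5, 6, 7, 8, ..., 27, 28, 29]
best small division:  k = 4: r2 = 0.983, p = 0.0083
verdict:              meaningful
```

The drift is real but buried: the full-series regression is extremely
significant (p = 1.6e-08) yet explains only 28% of the variance, failing
the r² ≥ 0.65 bar. Averaging the 100 points into 4 interval means lifts
r² to 0.983 at p = 0.0083 — both thresholds met, so the trend is declared
statistically meaningful. A flat or pure-noise series finds no qualifying
division (see `examples/sensitivity_grid.py`).

The other scripts in `examples/` each demonstrate one capability:
interval-division arithmetic on the canonical 7-point series, the
analytic critical-r² table (r² = 0.65 guarantees p ≤ 0.05 from 7 data
pairs on, but not at 3..6), the Monte Carlo characterisation of the
division sweep, and the sensitivity of verdicts to the (p, r²) limits.

There is also a thin CLI for shell use:

```sh
smtrend test --input series.csv --time-col year --value-col chl
smtrend synth --generator trend-uniform-noise --n 1000 --seed 1 --out mc.csv
smtrend simulate --experiment frequency --runs 1000 --out freq.csv
```

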
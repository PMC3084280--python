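# Methods

## The test

Given observations (tᵢ, yᵢ), i = 1..n, the package evaluates ordinary
least-squares regressions of value on time and declares the trend
*statistically meaningful* when any of the following fits reaches both
r² ≥ `r2_min` (default 0.65) and p ≤ `p_max` (default 0.05), comparisons
inclusive:

* the full-series fit of all n pairs;
* for every division count k in `k_min..min(k_max, n)` (defaults 3..30),
  the fit of the k interval midpoints against the k interval mean values.

r² is the squared Pearson correlation; the t statistic is recovered from
n and r² as t = √(r²·(n−2)/(1−r²)), and p is the two-tailed Student-t
tail at df = n − 2 (continuous distribution, not table lookup). t is
reported as a magnitude; trend direction is carried separately as the
slope sign. The verdict is a plain disjunction over the sweep: **no
multiple-testing correction is applied**, matching the test's original
formulation (see Limitations).

## Interval division

**Equal time steps** (regular series, one observation per time unit).
Observation i occupies the unit cell [i−1, i) on an axis of length n;
the axis is cut into k cells of length n/k and observation i's weight in
interval j is the overlap of the two cells. Every weight is a multiple
of 1/k, so the implementation computes integer overlap numerators on a
common grid (cell [i·k, (i+1)·k) versus interval [j·n, (j+1)·n)) and
forms each mean as an integer-weighted dot product divided by n. Weight
conservation is therefore exact, not approximate: rows sum to n, columns
to k. For n = 7, k = 3 this reproduces the canonical weights
(1, 1, ⅓)/(2+⅓), (⅔, 1, ⅔)/(2+⅓), (⅓, 1, 1)/(2+⅓).

**Different time steps** (uneven spacing and/or several samples per time
unit). The time range is cut into k equal-length sub-ranges, half-open
on the right except the last; each observation is assigned wholly to the
sub-range containing its time and means are unweighted. When all times
are integers the range is read as inclusive unit blocks, i.e.
[t_min, t_max + 1), so times 1..9 split into thirds as 1–3, 4–6, 7–9;
the `integer_blocks` argument exposes this toggle ("auto" resolves by
inspecting the times). A sub-range containing no observation does not
abort the test: that division is recorded as skipped with a reason and
the sweep continues.

Both methods yield strictly increasing, equally spaced midpoints. Since
r², t and p are invariant under affine maps of the predictor, regressing
against midpoints or against interval indices 1..k is equivalent; the
midpoint choice is cosmetic and documented as such.

**A note on collinearity.** Interval means of an exactly linear series
are exactly collinear in the midpoints only when k divides n (or in
symmetric cases such as n = 7, k = 3). When interval boundaries cut unit
cells fractionally, averaging the step-wise constant observations leaves
a quantisation residual of relative order k/n (e.g. 1 − r² ≈ 3e-8 at
n = 100, k = 6). This is a property of the weighting itself, not of the
implementation, and is orders of magnitude below every decision
threshold.

## Spacing classification

A series is *regular* when all times are distinct and consecutive
differences agree within relative tolerance 1e-9; otherwise *irregular*
(duplicate times always force irregular). Regular series route to the
equal-steps method, irregular ones to the different-steps method; the
caller can force either. The relative tolerance keeps the verdict
invariant under affine rescaling of the time axis, with the float64
caveat that offsets enormous relative to the step (≈1e9 steps) exhaust
the mantissa and can flip the classification.

## Degenerate inputs and numerical conventions

* Constant response: r² = 0, p = 1, flagged degenerate — a flat series
  is the canonical "no trend" and can never qualify.
* Constant predictor: an error; no regression is defined.
* Exactly collinear data (r² = 1): t is reported as infinite and p is
  clamped to the smallest positive double so that p ∈ (0, 1] holds
  throughout.
* The critical r² at which p equals a limit is computed analytically as
  t_c²/(t_c² + n − 2) from the critical two-tailed t. With the default
  limits this crosses 0.65 between 6 and 7 pairs: at 3..6 interval
  means, r² = 0.65 can still be non-significant (critical r² 0.994,
  0.903, 0.771, 0.658), while from 7 means on it always is significant
  (critical r² 0.569 and falling).
* File ingestion sorts by time (stable), drops rows with missing or
  non-finite entries (counted and logged), and treats a non-numeric cell
  as an error naming the row. Writing uses shortest round-trip float
  notation and reading uses the round-trip parser, so write→read is
  bit-identical.

## Synthetic data

`generate_trend_noise` (slope·t + Gaussian noise, regular step 1) and
`generate_irregular_series` (explicit uneven times, or n samples placed
with replacement on integer time units) produce unit-test and example
fixtures. All generators are seed-deterministic.

The Monte Carlo generator family emulates the construction used to
characterise the test: x = 1..n (default 1000) with two fresh
uniform(0, 1) draws per point, combined by a registered functional form
with a calibration constant (default 8281). The exact published form is
not recoverable, so the registry documents its default as a conjecture:

    y = x + 8281 · (Rand1 − Rand2)     ("trend-uniform-noise")

a unit drift in symmetric triangular noise of half-width 8281. The
constant plays its original calibrating role: at 8281 the division count
most likely to qualify (k = 6) does so in ≈50% of runs. At 1,000 runs
this form reproduces the published qualitative behaviour closely —
qualification peaking at k = 6 (≈52%) with k = 5 and 7 near 43%, decay
to a few percent beyond k = 14, the 6-interval r² exceeding each of the
20..25-interval r² in ≈99.7% of comparisons with shortfalls below 0.04
when it does not, and divisions 3..19 deciding essentially every
verdict. `pure-noise` (the noise term alone) and `perfect-line` forms
serve as controls, and new forms can be registered without touching the
experiment code.

What the generator does **not** emulate: autocorrelated or seasonal
noise, heteroscedasticity, irregular sampling, missing data, and
non-linear trends. Passing simulation tests therefore demonstrates the
test's behaviour under white-noise drift conditions only; on real
monitoring data with serial correlation, the plain OLS p-values the
method uses are anti-conservative.

## Experiment scale

The characterisation experiments default to 1,000 runs of length-1000
series over a division sweep of 3..25 — enough for binomial standard
errors near 1.6 percentage points on a 50% rate, and they run in seconds.
The identical code path supports published-scale settings (100,000 runs);
only the `runs` argument changes. Per-run seeds are derived from the
experiment seed via a seed sequence, so individual runs are reproducible
in isolation.

## Design choices that were genuinely open

* The unit-cell overlap weighting generalises the single printed
  worked example of the equal-steps method to all (n, k); it is the only
  extension that reproduces the example's ⅓/⅔ weights while conserving
  each observation's total weight exactly.
* The full-series regression participates in the verdict (the
  definition's disjunction names both the raw series and interval means);
  division-based results drive typical verdicts, but a short clean series
  can qualify outright.
* Slope-sign consistency across divisions is *not* required — the
  per-division signs are reported for the user instead.
* The division-frequency experiment tallies every qualifying k of a run
  (the per-division reading); a `tally="once_per_run"` mode credits only
  the best-qualifying k for users who prefer the run-level reading.
* `k_max` defaults to 30; sweeping higher is supported but costs time on
  very long series and, per the redundancy analysis, divisions beyond 19
  essentially never change a verdict.

## Limitations

* **Family-wise error.** Because the verdict is an uncorrected
  disjunction over ~28 division counts, its type-I rate on pure iid noise
  is far above the nominal 5% of a single test: at k = 3..6 the critical
  r² exceeds 0.65, so qualifying there is exactly a p ≤ 0.05 event, and
  the empirical family-wise rate on 1,000 pure-noise series (n = 100) is
  ≈16%. The verdict is a screening label, not a calibrated p-value.
* Plain OLS inference assumes independent errors; serially correlated
  residuals inflate both significance and the interval-mean r².
* The different-steps method discards within-interval timing: two
  observations at opposite ends of a sub-range count the same.
* The default Monte Carlo form is a documented conjecture; simulation
  outputs are labelled with the generator name, and exact published
  simulation counts are not reproducible from the printed description.
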
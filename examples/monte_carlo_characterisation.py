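"""Characterise the division sweep with the default Monte Carlo generator.

Draws 500 length-1000 series of the form y = x + 8281*(Rand1 - Rand2),
sweeps division counts 3..25, and summarises which counts detect the
drift: qualification peaks near k = 6 in about half the runs, the
6-interval r-squared almost always beats 20..25 intervals, and divisions
beyond 19 never rescue a verdict.
"""

import smtrend as st

spec = st.GeneratorSpec(n=1000, seed=7)
records = st.simulate_records(spec, runs=500)

counts = st.division_frequency_experiment(None, 0, records=records)
print("qualification counts per division number (500 runs):")
for k in sorted(counts):
    bar = "#" * (counts[k] // 8)
    print(f"  k={k:>2}  {counts[k]:>3}  {bar}")

dom = st.k6_dominance_experiment(None, 0, records=records)
red = st.redundancy_fraction(records, k_limit=19)
print(f"\nk=6 r2 exceeds each of k=20..25 in {100 * dom.fraction_exceeding:.1f}% "
      f"of {dom.comparisons} comparisons (max shortfall {dom.max_shortfall:.3f})")
print(f"capping the sweep at k<=19 preserves {100 * red:.1f}% of verdicts")
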
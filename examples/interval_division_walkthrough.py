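"""Walk through both interval-division methods on seven observations.

A regular series (times 1..7) is divided by the equal-time-steps method,
which splits the seven unit cells into three cells of length 7/3 and
weights boundary observations fractionally (weights 1/3 and 2/3 on y3 and
y5).  An uneven series (times 1,3,4,5,6,8,9) is divided by the
different-time-steps method into the unit blocks 1-3, 4-6, 7-9.
"""

import numpy as np

import smtrend as st

regular = st.TimeSeries(np.arange(1.0, 8.0), np.arange(1.0, 8.0), label="regular")
im = st.divide_equal_time_steps(regular, k=3)
numer = st.equal_steps_weight_numerators(7, 3)
print("equal time steps, n=7, k=3, y = 1..7")
print(f"  weights (x k=3):  {numer.tolist()}")
print(f"  interval means:   {im.means.tolist()}   (exactly 12/7, 4, 44/7)")
print(f"  support per cell: {im.support[0]:.4f} observations (7/3)")

uneven = st.TimeSeries(np.array([1.0, 3, 4, 5, 6, 8, 9]),
                       np.array([2.0, 4, 3, 5, 7, 6, 8]), label="uneven")
im2 = st.divide_different_time_steps(uneven, k=3)
print("\ndifferent time steps, times (1,3,4,5,6,8,9), k=3")
print(f"  groups hold {im2.support.astype(int).tolist()} observations "
      "(x = 1-3, 4-6, 7-9)")
print(f"  interval means:   {im2.means.tolist()}")
print(f"  spacing class:    {st.classify_spacing(uneven).kind}")

# Each weight row sums to n/k observations; every observation contributes
# exactly once across intervals, so no information is dropped or doubled.
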
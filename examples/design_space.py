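"""Build the 18-model time-of-day design space and print two designs.

Models 1-6 predict a deviation in one two-hour timespan, 7-11 in two
adjacent timespans, 12-17 are phase-shifted sinusoids (an idealized
circadian waveform), and 18 is the null model.
"""

import numpy as np

from chronodcm import allocate_timespan, enumerate_model_space, time_effect_column

space = enumerate_model_space()
print(f"{len(space.designs)} designs, rows = (timespan, session) cells\n")

print("model 7 (deviation over the two morning timespans, 09:00-13:00):")
print(space[7].to_dataframe().round(3))

print("\nmodel 12 time-effect column (sinusoid peaking at timespan 2):")
print(np.round(time_effect_column(12), 3))

print("\nmid-scan time 10:30 falls in timespan", allocate_timespan(10.5))
print("mid-scan time 20:15 falls in timespan", allocate_timespan(20.25))
# The printed matrices show the mean column, the mean-centred time-effect
# column, and five sum-to-zero codes for the six-level timespan factor; the
# two session rows of each timespan are identical, so LR/RL are averaged.
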
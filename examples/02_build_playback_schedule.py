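"""Build and inspect a full playback schedule for a female subject.

A female trial presents 6 call-type blocks (5 call types + song), each
with three 300-emission series — one per familiarity level (mate,
familiar, unfamiliar) — at 2 +/- 0.5 s intervals, with 70 +/- 10 s
between series and 130 +/- 10 s between blocks.
"""

import numpy as np

from softcalls.playback import build_schedule, default_exemplars

schedule = build_schedule("F", default_exemplars("F"), seed=11)
series = schedule.series_table()

print(f"series            : {schedule.n_series}")
print(f"total emissions   : {len(schedule.emissions)}")
print(f"trial duration    : {schedule.emissions['emission_s'].max() / 3600:.2f} h")
gaps = np.diff(schedule.emissions["emission_s"].to_numpy())
print(f"in-series gaps    : {gaps[gaps <= 2.5].min():.2f}-{gaps[gaps <= 2.5].max():.2f} s")
print()
print(series[["playback_order", "call_type", "familiarity", "start_s", "n_emissions"]].head(6).to_string(index=False))
print()
print("18 series of 300 emissions each; every series repeats 3 exemplar")
print("stimuli 100 times in random order, so familiarity effects cannot")
print("be confounded with a single recording.")
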
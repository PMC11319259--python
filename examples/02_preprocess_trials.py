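"""Preprocess raw trials into 101-point normalized channels.

Shows the event detection (start, peak, catch), the exclusion bookkeeping,
and the normalized channel ranges of one processed trial.
"""

import numpy as np

from liftsig.preprocess import CHANNELS, process_dataset
from liftsig.synthgen import GenParams, generate_dataset

raws = generate_dataset(GenParams(seed=1))
processed, exclusions = process_dataset(raws)
print(f"retained {len(processed)}/{len(raws)} trials; "
      f"{len(exclusions)} excluded (unsegmentable)")

trial = processed[0]
print(f"\ntrial {trial.key}: start {trial.start_time_s:.3f} s, "
      f"peak {trial.peak_time_s:.3f} s, catch {trial.catch_time_s:.3f} s")
print("channel ranges on the 0-100% movement grid:")
for ch in CHANNELS:
    v = trial.channels[ch]
    unit = {"position": "bh", "velocity": "bh/s", "GRF": "N/kg"}[ch.split(".")[0]]
    print(f"  {ch:12s}: {v.min():8.3f} .. {v.max():8.3f} {unit}")
print("\nPositions start at exactly 0 (baseline subtracted) and are fractions "
      "of body height; GRF.V around 9.81 N/kg is one body weight.")
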
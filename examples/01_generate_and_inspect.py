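"""Generate a synthetic snatch dataset and inspect one raw trial.

Builds the default study design (15 participants x 4 motor-learning
conditions x 3 trials) and prints the physical sanity numbers of a single
trial: quiet-stance force against system weight, peak vertical bar
displacement, and the flight-phase unloading if present.
"""

import numpy as np

from liftsig.synthgen import GRAVITY, GenParams, generate_dataset

params = GenParams(seed=1)
trials = generate_dataset(params)
print(f"generated {len(trials)} trials "
      f"({params.n_participants} participants x 4 conditions x {params.n_trials})")

raw = trials[0]
z = 0.5 * (raw.marker_left[:, 2] + raw.marker_right[:, 2])
total_v = raw.grf_plate1[:, 2] + raw.grf_plate2[:, 2]
weight = (raw.body_mass + raw.barbell_mass) * GRAVITY

print(f"\ntrial {raw.key}: height {raw.body_height:.2f} m, "
      f"mass {raw.body_mass:.1f} kg")
print(f"quiet-stance GRF  : {total_v[:50].mean():8.1f} N "
      f"(system weight {weight:.1f} N)")
print(f"peak bar lift     : {z.max() - z[0]:8.3f} m "
      f"({(z.max() - z[0]) / raw.body_height:.2f} body heights)")
print(f"GRF range         : {total_v.min():8.1f} .. {total_v.max():.1f} N "
      f"({total_v.min() / weight:.2f} .. {total_v.max() / weight:.2f} x weight)")
print("\nA GRF minimum near zero indicates a flight phase (feet leaving the "
      "plates); peaks around 1.5-2x weight are the pull.")
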
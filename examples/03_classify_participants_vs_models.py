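"""The core comparison: who lifted vs which training bout preceded the lift.

Runs the linear SVM under both leave-one-group-out designs on the full
six-channel input and prints the accuracy tables next to their chance
baselines.  The expected picture: participants are highly classifiable
(individual movement signatures), the motor-learning condition is barely
above chance.
"""

import numpy as np

from liftsig.classify import run_experiment, zero_rule_accuracy
from liftsig.preprocess import process_dataset
from liftsig.synthgen import GenParams, generate_dataset

processed, _ = process_dataset(generate_dataset(GenParams(seed=1)))

for task in ("participant", "model"):
    rep = run_experiment(processed, task, "All")
    zr = zero_rule_accuracy(processed, task)
    print(f"\n=== {task} task (combo: All, folds x 3 scalings) ===")
    for s in rep.scalings:
        m, sd = rep.scaling_mean_sd(s)
        folds = " ".join(f"{a:5.1f}" for a in rep.accuracies[s])
        print(f"  {s:8s}: {folds}   mean {m:5.1f} +/- {sd:4.1f} %")
    print(f"  averaged accuracy: {rep.averaged_accuracy:.1f} +/- "
          f"{rep.averaged_sd:.1f} %   (zero-rule baseline {zr:.1f} %)")

print("\nA large participant-vs-model gap reproduces the individuality-"
      "dominant structure of the generator.")
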
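# liftsig

**Individual movement signatures in barbell power-snatch trials: synthetic
recordings, trajectory preprocessing, linear-SVM classification, and LRP
explanations.**

## The scientific problem

When novices learn a whole-body strength-coordination skill such as the
Olympic power snatch, is their barbell technique already *individual* — more
recognisable by **who** lifted than by **which training intervention**
preceded the lift?  The question is answered with a classification
experiment: time-continuous barbell kinematics (position, velocity) and
ground-reaction forces (GRF) from standardized trials are fed to a linear
classifier under two leave-one-group-out cross-validation designs:

* **participant task** — predict the lifter (15 classes).  4 folds, each
  testing all trials recorded after one motor-learning condition
  (bCIL, sCIL, DL, RL), so the classifier must recognise a person across an
  intervention it never saw: 135 training / 45 test trials per fold.
* **model task** — predict the motor-learning condition (4 classes: RL =
  repetitive learning, bCIL/sCIL = blocked/serial contextual-interference
  learning, DL = differential learning).  5 folds, each testing one fixed
  group of 3 held-out participants: 144 training / 36 test trials per fold.

Large participant-task accuracy together with chance-level model-task
accuracy supports the *individuality hypothesis*: personal movement
signatures dominate over short-term intervention effects.

This package is a tested re-implementation of that analysis pipeline.
Because the original motion-capture recordings are not publicly available,
a first-class **synthetic-trial generator** defines the study conditions and
makes every downstream stage verifiable.

## Pipeline

1. **synthgen** — raw trials: two barbell-end markers (250 Hz) and two
   force plates (1000 Hz) per trial, for 15 participants x 4 conditions x 3
   trials.  Vertical bar position is a rising logistic (pull) minus a
   steeper later logistic (drop into the catch) plus a small catch bounce;
   vertical GRF is system weight modulated by two Gaussian pull peaks and an
   optional flight-phase dip.  Variance enters at participant, condition,
   and trial level, with the participant level dominant
   (σ_ind = 0.08 > σ_cond = 0.02 > σ_trial = 0.01, relative).
2. **preprocess** — marker averaging, plate summation, zero-phase 4th-order
   Butterworth filtering (4 Hz position / 15 Hz GRF), central-difference
   velocity, event segmentation (start: vertical velocity ≥ 0.01 m/s;
   catch: first return to non-negative vertical velocity after the negative
   phase following maximal displacement), body-size normalization (position
   and velocity by body height, GRF by body mass), resampling to 101 points
   (0–100% of movement), baseline subtraction of the position channels.
   Unsegmentable trials are excluded with a logged reason.
3. **features / classify** — 15 registered channel combinations (9
   kinematic, 3 kinetic, 3 mixed) x 3 scaling approaches (none; batch =
   channel max-abs over the *training* split; instance = per-trial channel
   max-abs), classified by a one-vs-rest linear SVM (L2 penalty, squared
   hinge, C = 1, no tuning).  Accuracy is reported per fold and scaling;
   the *averaged accuracy* is the arithmetic mean over all fold x scaling
   values.
4. **lrp** — layer-wise relevance propagation for the linear models:
   R_i = W_c,i · x_i for the ground-truth class c (Σ R_i equals the decision
   score minus bias exactly), positive relevances normalized per trial and
   averaged over all test trials of all folds into channel-wise profiles.

## Worked example

```bash
python examples/03_classify_participants_vs_models.py
```

prints (seed 1):

```
=== participant task (combo: All, folds x 3 scalings) ===
  none    :  97.8 100.0 100.0  97.8   mean  98.9 +/-  1.3 %
  batch   :  97.8 100.0  93.3  93.3   mean  96.1 +/-  3.3 %
  instance: 100.0  95.6  97.8  93.3   mean  96.7 +/-  2.9 %
  averaged accuracy: 97.2 +/- 2.7 %   (zero-rule baseline 6.7 %)

=== model task (combo: All, folds x 3 scalings) ===
  ...
  averaged accuracy: 41.3 +/- 9.9 %   (zero-rule baseline 25.0 %)
```

Reading: the classifier identifies the simulated lifter almost perfectly
across held-out conditions (97.2% vs a 1-in-15 chance of 6.7%), while the
motor-learning condition is only weakly recoverable from held-out
participants (41.3% vs 25% chance) — the individuality-dominant structure
the generator encodes.  `examples/01`, `02` and `04` walk through
generation, preprocessing, and the LRP profiles.

A thin CLI wraps the same library calls:

```bash
liftsig synth --out raw/              # CSV per trial + manifest.json
liftsig preprocess --in raw/ --out processed.csv
liftsig classify --task participant --combo All --scaling all \
    --in processed.csv --out results/
liftsig run --config cfg.yaml         # full pipeline, all artifacts
```

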
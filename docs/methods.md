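# Methods

This note documents the models, parameters, and numerical choices behind
`liftsig`, and what the synthetic study can and cannot show about real
recordings.

## Synthetic trial model

Each trial simulates the raw output of a barbell power-snatch measurement:
two barbell-end marker trajectories at 250 Hz and two force-plate GRF
vectors at 1000 Hz over a 2.3 s window, with a quiet stance of 0.25 s before
movement onset.  Axes are (AP, ML, V): anterior-posterior, medio-lateral,
vertical.  The medio-lateral channels exist for marker realism only and are
never consumed by the analysis.

### Vertical bar path

z(t) = z₀ + H·[h_peak·L(t; t_rise, τ_rise) − d_drop·L(t; t_drop, τ_drop)
        + a_bounce·G(t; t_drop + 0.35 s, 0.12 s)]

with L a logistic, G a Gaussian bump, H body height, and z₀ = 0.23 m (bar
resting height).  The two logistics guarantee the event structure the
segmentation needs: a positive-velocity pull, a displacement maximum, a
negative-velocity drop, and a return of the vertical velocity to zero (the
catch).  The small bounce term (a_bounce = 0.012 body heights, fixed)
models the damped settling of a caught bar.  It also serves a numerical
purpose: without it the velocity re-crosses zero along the flat asymptotic
tail of the logistics, where sub-millimetre marker noise moves the detected
catch by ~0.1 s and destroys the time-normalized alignment of repeated
trials.  With the bounce, the crossing slope is steep and the catch is
stable to ~1 sample.

### AP path and GRF

The AP bar path is a biphasic difference of Gaussians (toward the lifter
during the pull, forward at the turnover) scaled by a_ap·H.  The vertical
GRF is system weight (body + 20 kg barbell) modulated by two Gaussian pull
peaks (A1, A2, in multiples of system weight) and, for lifters whose
technique includes a flight phase, a Gaussian unloading dip (depth
F_flight, clipped to [0, 1]) centred at 1.2 s — after the second pull peak,
so the default depth 0.9 takes the force below 0.2x system weight.  The AP
GRF is a biphasic Gaussian difference scaled by a_grf_ap (N/kg).  The total
force is split between the plates at a ratio 0.5 plus slow noise.

### Variance structure

A 15-component shape vector θ (amplitudes, timings, widths) varies at three
nested levels, all *relative* to the baseline θ₀ and all component-scaled:

| level        | SD (relative) | mechanism |
|--------------|---------------|-----------|
| participant  | σ_ind = 0.08  | Gaussian offset per participant, truncated to structurally valid shapes |
| condition    | σ_cond = 0.02 | fixed sign vector per condition (each component shifted by exactly ±σ_cond) |
| trial        | σ_trial = 0.01| Gaussian jitter per trial |

Two deliberate design choices:

* **Component scales.**  The six timing components (logistic centres and
  time constants, GRF peak centres) carry a fixed multiplier of 0.15; raw
  8% relative timing variability destroys the negative-velocity phase in a
  sizeable fraction of draws (the event geometry is exponentially sensitive
  to the rise/drop gap) and, through the steep GRF-peak slopes, lets the
  condition shift swamp amplitude information.  Physically, movement timing
  under a fixed load is far more constrained than amplitudes; amplitudes
  and widths vary at full scale and carry the individuality signal.
* **Condition offsets as sign vectors.**  Each component moves by exactly
  ±σ_cond.  This keeps the per-component condition effect above the trial
  jitter (so a one-way variance decomposition of any scalar trial summary
  orders participant > condition > trial) while guaranteeing that no single
  component is shifted by more than σ_cond — Gaussian directions
  occasionally concentrate 2–3x σ_cond in one component and then collapse
  single held-out-condition folds.

The flight phase is a *participant trait* (probability 0.5 per
participant): per-trial random flight would make trial-level GRF variance
the largest component, contradicting the individuality-dominant regime the
generator is meant to encode.

Participant shape vectors are rejection-sampled: a draw must produce, at
zero noise, a segmentable trial with a negative-velocity phase of at least
0.04 body heights/s and a displacement peak clearing everything after the
catch by 1.5% of body height.  About 2–5% of draws are redrawn under the
defaults; individuality is therefore a truncated Gaussian (lifters whose
shape could not arrest the bar do not occur).

Marker path noise is white noise of SD 2 mm low-pass filtered at 2 Hz
(postural-sway band) — the filtering attenuates it to ~0.25 mm RMS,
matching the residual jitter of averaged optical markers.  Velocity noise
after the analysis filter stays well below the 0.01 m/s onset threshold, so
the start event is signal-driven.  Anthropometry: height ~ N(1.80, 0.06²) m,
BMI ~ N(24.1, 2.2²) kg/m², clipped to [1.5, 2.1] m and [55, 110] kg.

## Preprocessing

* Zero-phase (forward-backward) 4th-order Butterworth filtering — 4 Hz for
  positions, 15 Hz for GRF.  Zero-phase is standard in biomechanics because
  phase lag would shift the detected events; the resulting amplitude
  response is squared (gain 1/2 at the cutoff).
* Velocity by central differences on the filtered position (one-sided at
  the series ends), before trimming.
* Events on sampled data: start = first sample with vertical velocity
  ≥ 0.01 m/s; catch = first sample back at ≥ 0 after the first negative
  sample following the displacement argmax.  No sub-sample interpolation;
  comparisons are exact.  The onset threshold is dimensional (a protocol
  constant in m/s), so the pipeline is deliberately *not* invariant to
  rescaling raw positions; the normalization step itself is.
* GRF trimming maps the marker-grid event times to the 1000 Hz grid by
  nearest index.
* Normalization: position and velocity ÷ body height (units: body heights,
  bh), GRF ÷ body mass (N/kg, i.e. not body-weight multiples); each channel
  linearly resampled to 101 points; the point-0 value subtracted from both
  position channels.
* A trial whose events cannot be identified raises a segmentation error and
  is excluded with a logged reason; retained + excluded always equals the
  input count.

## Classification

LinearSVC (liblinear) with L2 penalty, squared-hinge loss, C = 1, tolerance
1e-4, pinned internal seed, no centering or tuning; one-vs-rest for the
multiclass tasks, with prediction by argmax over per-class decision scores
(ties to the lowest class index).  Batch-scaling statistics are computed
per fold from the training split only.  The reported SD is the sample
standard deviation (n−1) over fold values (per scaling) or over all
fold x scaling values (averaged accuracy).  Model-task participant groups
are the sorted participants chunked in threes unless an explicit group map
is supplied.

## LRP

For a linear model the relevance of feature i toward class c is
R_i = W_c,i·x_i; the bias receives no relevance, so Σ R_i equals the
decision score minus bias to machine precision (asserted in the tests).
Following the explainability protocol for the participant task, negative
relevances are discarded, the positive part is normalized to the trial's
maximum positive relevance (all-zero guard if none), and profiles are the
feature-wise mean over all test trials of all folds, pooled — normalization
happens per trial, before any averaging.  Inputs enter LRP exactly as the
SVM saw them, so profiles are computed per scaling approach.

## Problem sizes and runtime

All defaults run the full 180-trial design.  The test suite uses the full
design where the contract demands it (fold sizes, chance baselines,
parameter recovery over three seeds) and reduced designs (6–10
participants, 2 trials) for property checks such as monotone signal
recovery; the whole suite runs in about five minutes on one CPU, and
`scripts/acceptance.py` in under one.

## What passing tests do and do not show

The generator encodes the structure the analysis is designed to detect —
dominant, persistent individual shape differences with a weak condition
effect.  Passing parameter-recovery tests therefore shows that the pipeline
*faithfully recovers a known ground truth*, including the asymmetry between
near-perfect participant classification and near-chance condition
classification with the condition effect removed.  It does not show that
real novice lifters are individual: real recordings add whole-body degrees
of freedom, non-stationary learning effects within a session, richer
nuisance variability (electrode-free but marker-occlusion-prone capture,
plate crosstalk), and flight-phase behaviour that varies within a lifter.
The synthetic condition effect is also a crude stand-in: a fixed shape
offset per condition, not a model of what contextual-interference or
differential learning actually changes.

## Known limitations

* The generative curves are low-dimensional; channel covariances within a
  trial are stronger than in real data, which flatters classifiers.
* Condition offsets are frozen per seed; across-seed variability of the
  model-task accuracy is driven as much by these four vectors as by trial
  sampling.
* Exclusion handling mirrors the protocol (drop the trial, log the reason)
  but the generator's defaults are calibrated so that exclusions are rare;
  the exclusion path is exercised in tests with constructed inputs.
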
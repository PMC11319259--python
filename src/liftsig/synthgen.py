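"""Synthetic power-snatch trial generator.

Emulates the raw recordings of a barbell power-snatch session: two barbell-end
marker trajectories (250 Hz) and two force-plate ground-reaction-force vectors
(1000 Hz) per trial, for a cohort of participants each lifting under four
motor-learning conditions with a small number of standardized trials.

The signal model is a low-dimensional shape parameterization chosen so that
every noise-free trial has the event structure the downstream segmentation
requires: vertical barbell position is a rising logistic (the pull) minus a
later, steeper logistic (the drop into the catch), which guarantees a positive
velocity phase, a displacement maximum, a negative velocity phase, and a
return of the vertical velocity to zero. The vertical GRF is system weight
modulated by two Gaussian pull peaks and an optional flight-phase dip.

Variance enters at three nested levels — participant, condition, and trial —
as relative perturbations of the shape vector, with the participant level
dominant by default (an "individuality-dominant" regime).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal

__all__ = [
    "CONDITIONS",
    "THETA_COMPONENTS",
    "GenParams",
    "ParticipantProfile",
    "RawTrial",
    "GenerationError",
    "make_cohort",
    "condition_offsets",
    "generate_trial",
    "generate_dataset",
]

#: Motor-learning conditions labelling the standardized trials: repetitive
#: learning, blocked and serial contextual-interference learning, and
#: differential learning.
CONDITIONS = ("RL", "bCIL", "sCIL", "DL")

GRAVITY = 9.81  # m/s^2

#: Names of the shape-vector components, in storage order.
THETA_COMPONENTS = (
    "h_peak",     # peak vertical barbell displacement, fraction of body height
    "d_drop",     # peak-to-catch vertical drop, fraction of body height
    "t_rise",     # centre of the rising logistic, s
    "tau_rise",   # time constant of the rising logistic, s
    "t_drop",     # centre of the dropping logistic, s
    "tau_drop",   # time constant of the dropping logistic, s
    "a_ap",       # anterior-posterior excursion amplitude, fraction of body height
    "A1",         # first vertical-GRF pull-peak amplitude, multiples of system weight
    "A2",         # second vertical-GRF pull-peak amplitude, multiples of system weight
    "t_p1",       # centre of the first pull peak, s
    "t_p2",       # centre of the second pull peak, s
    "w_p1",       # width of the first pull peak, s
    "w_p2",       # width of the second pull peak, s
    "F_flight",   # flight-phase dip depth, fraction of system weight (0-1)
    "a_grf_ap",   # anterior-posterior GRF amplitude, N/kg
)

_THETA_0 = {
    "h_peak": 0.70,
    "d_drop": 0.08,
    "t_rise": 0.90,
    "tau_rise": 0.12,
    "t_drop": 1.35,
    "tau_drop": 0.08,
    "a_ap": 0.08,
    "A1": 0.45,
    "A2": 0.60,
    "t_p1": 0.60,
    "t_p2": 1.00,
    "w_p1": 0.12,
    "w_p2": 0.08,
    "F_flight": 0.90,
    "a_grf_ap": 1.50,
}


#: Fixed per-component variance multipliers (see GenParams.component_scale).
#: Timing components vary far less (relatively) than amplitudes: movement
#: timing under a fixed load is tightly constrained, and undamped timing
#: variability both destroys the event structure segmentation needs and
#: swamps amplitude information through the steep slopes of the GRF peaks.
_TIMING = ("t_rise", "tau_rise", "t_drop", "tau_drop", "t_p1", "t_p2")
_COMPONENT_SCALE = {name: (0.15 if name in _TIMING else 1.0)
                    for name in THETA_COMPONENTS}


class GenerationError(RuntimeError):
    """Raised when a drawn shape vector cannot produce a segmentable trial."""


def _theta_array(theta: Mapping[str, float]) -> np.ndarray:
    return np.array([float(theta[k]) for k in THETA_COMPONENTS])


@dataclass(frozen=True)
class GenParams:
    """Generator configuration: baseline shape, variance scales, and layout.

    The variance scales are *relative*: a scale of 0.08 perturbs each shape
    component by a zero-mean Gaussian with SD equal to 8% of its baseline
    value.  Defaults put between-participant variability well above
    between-condition and trial-to-trial variability.
    """

    theta_0: Mapping[str, float] = field(default_factory=lambda: dict(_THETA_0))
    sigma_ind: float = 0.08      # between-participant SD scale (relative)
    sigma_cond: float = 0.02     # between-condition SD scale (relative)
    sigma_trial: float = 0.01    # trial-to-trial SD scale (relative)
    sigma_path: float = 0.002    # additive smooth marker path noise SD, m
    flight_prob: float = 0.5     # probability a trial contains a flight phase
    seed: int = 0
    n_participants: int = 15
    n_trials: int = 3
    marker_fs: float = 250.0     # Hz
    force_fs: float = 1000.0     # Hz
    duration: float = 2.3        # s, trial window
    t_offset: float = 0.25
    """Stance shift, s: all timing components are measured from this instant,
    so the window opens with a genuine quiet stance (vertical velocity well
    below the 0.01 m/s onset threshold for at least t_offset seconds)."""
    catch_rebound: float = 0.012  # m-per-body-height amplitude of the catch bounce
    t_rebound: float = 0.35       # s after t_drop: centre of the catch bounce
    w_rebound: float = 0.12       # s, width of the catch bounce
    """The caught bar settles with a small damped bounce.  Besides realism,
    the bounce makes the vertical velocity re-cross zero with a decisive
    slope, so the catch event is robust to marker noise instead of hinging
    on the flat asymptotic tail of the two logistics."""
    bar_width: float = 2.2       # m, marker-to-marker distance along the ML axis
    barbell_mass: float = 20.0   # kg, standardized trial load
    bar_height0: float = 0.23    # m, resting barbell-centre height (bar radius + plate)
    t_flight: float = 1.20       # s, flight-dip centre
    w_flight: float = 0.05       # s, flight-dip width
    noise_cutoff_hz: float = 2.0  # path-noise low-pass cutoff (postural-sway band)
    component_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(_COMPONENT_SCALE))
    """Fixed per-component multipliers applied to every variance level.

    The timing components of the two position logistics get a factor of
    0.15: the negative-velocity phase the segmentation relies on depends
    exponentially on the rise/drop timing gap, so raw 8% relative timing
    variability would destroy the event structure in a sizeable fraction of
    draws, while amplitude variability is structurally harmless and carries
    the individuality signal at full scale.
    """
    ind_scale: Mapping[str, float] | None = None
    """Optional extra multipliers on the individuality level only.

    Setting e.g. ``{"a_ap": 0, ...}`` with ones elsewhere confines
    individuality to chosen shape components; used to construct datasets
    whose discriminative signal lives only in known channels.
    """

    def __post_init__(self) -> None:
        for name in ("sigma_ind", "sigma_cond", "sigma_trial", "sigma_path"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.flight_prob <= 1.0:
            raise ValueError("flight_prob must be in [0, 1]")
        missing = set(THETA_COMPONENTS) - set(self.theta_0)
        if missing:
            raise ValueError(f"theta_0 missing components: {sorted(missing)}")

    @property
    def theta0_vec(self) -> np.ndarray:
        return _theta_array(self.theta_0)

    @property
    def component_scale_vec(self) -> np.ndarray:
        return np.array([float(self.component_scale.get(k, 1.0))
                         for k in THETA_COMPONENTS])

    @property
    def ind_scale_vec(self) -> np.ndarray:
        if self.ind_scale is None:
            return np.ones(len(THETA_COMPONENTS))
        return np.array([float(self.ind_scale.get(k, 1.0)) for k in THETA_COMPONENTS])


@dataclass(frozen=True)
class ParticipantProfile:
    """A synthetic participant: anthropometry plus an individual shape vector.

    ``has_flight`` is a technique trait: whether this lifter's catch includes
    a flight phase (feet leaving the plates).  Modelling it at the
    participant level keeps trial-to-trial variance the smallest component,
    as the individuality-dominant regime requires.
    """

    participant_id: int
    body_height: float  # m
    body_mass: float    # kg
    theta_p: np.ndarray  # shape vector, THETA_COMPONENTS order
    has_flight: bool = False


@dataclass
class RawTrial:
    """One unprocessed trial: marker and plate series plus labels.

    Position arrays have shape (n, 3) with columns (AP, ML, V) in metres at
    ``marker_fs``; force arrays have shape (m, 3) in newtons at ``force_fs``.
    """

    marker_left: np.ndarray
    marker_right: np.ndarray
    grf_plate1: np.ndarray
    grf_plate2: np.ndarray
    marker_fs: float
    force_fs: float
    body_height: float
    body_mass: float
    barbell_mass: float
    participant_id: int
    condition: str
    trial_index: int

    @property
    def key(self) -> str:
        return f"P{self.participant_id:02d}_{self.condition}_T{self.trial_index}"


def _logistic(t: np.ndarray, centre: float, tau: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - centre) / tau))


def _bump(t: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - centre) / width) ** 2)


def _clamp_theta(theta: np.ndarray) -> np.ndarray:
    """Keep a perturbed shape vector physically and structurally plausible.

    Flight depth cannot exceed full unloading; amplitudes and time scales
    stay positive.  Leaves in-range vectors untouched.
    """
    th = dict(zip(THETA_COMPONENTS, theta))
    th["h_peak"] = max(th["h_peak"], 0.05)
    th["d_drop"] = min(max(th["d_drop"], 0.0), 0.8 * th["h_peak"])
    th["tau_rise"] = max(th["tau_rise"], 0.02)
    th["tau_drop"] = max(th["tau_drop"], 0.02)
    th["A1"] = max(th["A1"], 0.0)
    th["A2"] = max(th["A2"], 0.0)
    th["w_p1"] = max(th["w_p1"], 0.02)
    th["w_p2"] = max(th["w_p2"], 0.02)
    th["F_flight"] = min(max(th["F_flight"], 0.0), 1.0)
    return _theta_array(th)


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, cutoff: float,
                  sd: float, ncols: int = 1) -> np.ndarray:
    """White noise of SD ``sd`` low-pass filtered to ``cutoff`` Hz.

    The filtering strongly attenuates the white sequence (only the sub-cutoff
    band survives), mimicking residual marker jitter: smooth, with an RMS
    well below the raw noise floor.
    """
    if sd == 0.0 or n == 0:
        return np.zeros((n, ncols))
    pad = int(fs)  # 1 s of padding each side avoids filter edge transients
    white = sd * rng.standard_normal((n + 2 * pad, ncols))
    sos = _signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, white, axis=0)[pad:pad + n]


def _trial_curves(theta: np.ndarray, body_height: float, body_mass: float,
                  params: GenParams, flight_flag: bool):
    """Noise-free marker-centre and total-GRF curves for one shape vector."""
    th = dict(zip(THETA_COMPONENTS, theta))
    n_m = int(round(params.duration * params.marker_fs))
    n_f = int(round(params.duration * params.force_fs))
    # Timing components are measured from the end of the quiet stance.
    t_m = np.arange(n_m) / params.marker_fs - params.t_offset
    t_f = np.arange(n_f) / params.force_fs - params.t_offset

    H = body_height
    z = params.bar_height0 + H * (
        th["h_peak"] * _logistic(t_m, th["t_rise"], th["tau_rise"])
        - th["d_drop"] * _logistic(t_m, th["t_drop"], th["tau_drop"])
        + params.catch_rebound * _bump(t_m, th["t_drop"] + params.t_rebound,
                                       params.w_rebound)
    )
    # Biphasic AP path: toward the lifter during the pull, forward at the turnover.
    x = H * th["a_ap"] * (-_bump(t_m, th["t_rise"], 0.20)
                          + 0.9 * _bump(t_m, th["t_drop"], 0.15))
    centre = np.column_stack([x, np.zeros(n_m), z])

    weight = (body_mass + params.barbell_mass) * GRAVITY
    fz = weight * (
        1.0
        + th["A1"] * _bump(t_f, th["t_p1"], th["w_p1"])
        + th["A2"] * _bump(t_f, th["t_p2"], th["w_p2"])
        - (th["F_flight"] * _bump(t_f, params.t_flight, params.w_flight)
           if flight_flag else 0.0)
    )
    fx = body_mass * th["a_grf_ap"] * (_bump(t_f, th["t_p1"], 0.12)
                                       - _bump(t_f, th["t_p2"], 0.10))
    grf = np.column_stack([fx, np.zeros(n_f), fz])
    return centre, grf


def _segmentable(theta: np.ndarray, body_height: float, body_mass: float,
                 params: GenParams) -> bool:
    """True when the noise-free trial yields robust start/catch events.

    Beyond event existence, two safety margins guarantee that trial-level
    perturbations and path noise cannot destroy the event structure: the
    negative-velocity phase must reach at least 0.04 body heights/s, and the
    displacement maximum must clear everything after the catch by at least
    1.5% of body height.
    """
    from . import preprocess  # local import: preprocess does not import synthgen

    centre, _ = _trial_curves(theta, body_height, body_mass, params, flight_flag=False)
    pos_v = preprocess.lowpass(centre[:, 2], params.marker_fs,
                               preprocess.FilterSpec().cutoff_position_hz)
    vel_v = preprocess.differentiate(pos_v, params.marker_fs)
    try:
        start, catch = preprocess.segment_trial(vel_v, pos_v, params.marker_fs)
    except preprocess.SegmentationError:
        return False
    i_max = int(np.argmax(pos_v))
    if not start < i_max < catch:
        return False
    if vel_v[i_max:catch + 1].min() > -0.04 * body_height:
        return False
    if pos_v[i_max] - pos_v[catch:].max() < 0.015 * body_height:
        return False
    return True


def make_cohort(n_participants: int, params: GenParams) -> list[ParticipantProfile]:
    """Draw a cohort of participants with individual shape vectors.

    Each participant's shape vector is ``theta_0`` perturbed component-wise by
    a relative Gaussian offset with SD ``sigma_ind`` (optionally re-weighted
    per component by ``ind_scale``), conditioned on producing a robustly
    segmentable trial at zero noise: structurally invalid draws (a few
    percent under the defaults — shapes whose catch would not arrest the
    bar) are redrawn, i.e. individuality follows a truncated Gaussian.
    Anthropometry is drawn from ranges plausible for young, highly active
    adults.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 1]))
    theta0 = params.theta0_vec
    scale = params.component_scale_vec * params.ind_scale_vec
    profiles: list[ParticipantProfile] = []
    for pid in range(1, n_participants + 1):
        height = float(np.clip(rng.normal(1.80, 0.06), 1.5, 2.1))
        bmi = rng.normal(24.1, 2.2)
        mass = float(np.clip(bmi * height**2, 55.0, 110.0))
        has_flight = bool(rng.random() < params.flight_prob)
        for _attempt in range(100):
            delta = rng.standard_normal(len(theta0)) * params.sigma_ind * scale
            theta_p = _clamp_theta(theta0 * (1.0 + delta))
            if _segmentable(theta_p, height, mass, params):
                break
        else:
            raise GenerationError(
                f"participant {pid}: no segmentable shape vector in 100 draws; "
                "baseline parameters admit no valid movement")
        profiles.append(ParticipantProfile(pid, height, mass, theta_p, has_flight))
    return profiles


def condition_offsets(params: GenParams) -> dict[str, np.ndarray]:
    """Fixed per-condition relative shape offsets, frozen per seed.

    Each condition gets a random sign vector (every component shifted by
    exactly +/- ``sigma_cond``), so a single shape component carries a
    condition effect of size ``sigma_cond`` — above the trial-level jitter
    but well below individuality under the defaults, with no component ever
    exceeding that size.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 2]))
    out: dict[str, np.ndarray] = {}
    scale = params.component_scale_vec
    d = len(THETA_COMPONENTS)
    for cond in CONDITIONS:
        signs = rng.integers(0, 2, size=d) * 2.0 - 1.0
        out[cond] = params.sigma_cond * scale * signs
    return out


def generate_trial(profile: ParticipantProfile, condition: str, trial_index: int,
                   params: GenParams,
                   _offsets: Mapping[str, np.ndarray] | None = None,
                   flight: bool | None = None) -> RawTrial:
    """Generate one raw trial for a participant under a condition.

    The effective shape vector is the participant's ``theta_p`` plus the
    condition offset and a trial-level perturbation, both expressed relative
    to the baseline shape.  Smooth path noise is added to the marker
    coordinates; the total GRF is split between the two plates at a ratio
    0.5 plus smooth noise.  ``flight`` overrides the participant's flight
    trait when given.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if trial_index < 1:
        raise ValueError("trial_index must be >= 1")
    offsets = condition_offsets(params) if _offsets is None else _offsets
    cond_idx = CONDITIONS.index(condition)
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(params.seed), 3, int(profile.participant_id), cond_idx, int(trial_index)]))

    theta0 = params.theta0_vec
    eps = rng.standard_normal(len(theta0)) * params.sigma_trial * params.component_scale_vec
    theta = _clamp_theta(profile.theta_p + theta0 * (offsets[condition] + eps))
    if theta[THETA_COMPONENTS.index("t_drop")] <= theta[THETA_COMPONENTS.index("t_rise")]:
        raise GenerationError("t_drop must exceed t_rise")

    flight_flag = profile.has_flight if flight is None else bool(flight)
    centre, grf = _trial_curves(theta, profile.body_height, profile.body_mass,
                                params, flight_flag)
    n_m = centre.shape[0]
    n_f = grf.shape[0]

    half = np.array([0.0, params.bar_width / 2.0, 0.0])
    noise_l = _smooth_noise(rng, n_m, params.marker_fs, params.noise_cutoff_hz,
                            params.sigma_path, ncols=3)
    noise_r = _smooth_noise(rng, n_m, params.marker_fs, params.noise_cutoff_hz,
                            params.sigma_path, ncols=3)
    marker_left = centre - half + noise_l
    marker_right = centre + half + noise_r

    # Plate asymmetry wanders slowly at trial level; sigma_trial = 0 makes
    # repeated trials of one (participant, condition) cell exactly identical.
    ratio = 0.5 + _smooth_noise(rng, n_f, params.force_fs, params.noise_cutoff_hz,
                                params.sigma_trial, ncols=1)[:, 0]
    ratio = np.clip(ratio, 0.3, 0.7)
    plate1 = grf * ratio[:, None]
    plate2 = grf - plate1  # exact complement: plates always sum to the total

    return RawTrial(
        marker_left=marker_left, marker_right=marker_right,
        grf_plate1=plate1, grf_plate2=plate2,
        marker_fs=params.marker_fs, force_fs=params.force_fs,
        body_height=profile.body_height, body_mass=profile.body_mass,
        barbell_mass=params.barbell_mass,
        participant_id=profile.participant_id, condition=condition,
        trial_index=trial_index,
    )


def generate_dataset(params: GenParams) -> list[RawTrial]:
    """Generate the full factorial dataset (participants x conditions x trials).

    Defaults produce 15 x 4 x 3 = 180 trials.  The returned order is a
    deterministic shuffle of the factorial enumeration, driven by the seed.
    """
    cohort = make_cohort(params.n_participants, params)
    offsets = condition_offsets(params)
    trials: list[RawTrial] = []
    for profile in cohort:
        for condition in CONDITIONS:
            for t in range(1, params.n_trials + 1):
                trials.append(generate_trial(profile, condition, t, params,
                                             _offsets=offsets))
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 4]))
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]
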
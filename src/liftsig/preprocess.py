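"""Trajectory preprocessing: raw trials to 101-point normalized channels.

Pipeline per trial: average the two barbell-end markers to the bar centre,
sum the two plates to the total GRF, low-pass filter (zero-phase 4th-order
Butterworth; 4 Hz position, 15 Hz GRF), differentiate the filtered position,
segment the movement from the start event (vertical velocity >= 0.01 m/s) to
the catch event (first zero-crossing back to non-negative vertical velocity
after the negative phase that follows maximal vertical displacement), trim,
normalize position/velocity by body height and GRF by body mass, resample
each channel to 101 points (0-100% of the movement), and subtract the
initial value from both position channels.

Trials whose events cannot be identified raise :class:`SegmentationError`
and are excluded (with reason) by :func:`process_dataset`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "CHANNELS",
    "N_POINTS",
    "FilterSpec",
    "ProcessedTrial",
    "SegmentationError",
    "barbell_centre",
    "total_grf",
    "lowpass",
    "differentiate",
    "segment_trial",
    "normalize_and_trim",
    "process_trial",
    "process_dataset",
]

log = logging.getLogger(__name__)

#: Channel names in canonical (feature-assembly) order.
CHANNELS = ("position.AP", "position.V", "velocity.AP", "velocity.V",
            "GRF.AP", "GRF.V")

#: Number of points on the percent-of-movement grid.
N_POINTS = 101

# Column indices of the (AP, ML, V) axis convention used by the raw arrays.
_AP, _ML, _V = 0, 1, 2

START_VELOCITY_THRESHOLD = 0.01  # m/s, vertical velocity defining movement onset


class SegmentationError(RuntimeError):
    """Start or catch event could not be identified in a trial."""


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass design for position and GRF streams."""

    order: int = 4
    cutoff_position_hz: float = 4.0
    cutoff_grf_hz: float = 15.0


@dataclass
class ProcessedTrial:
    """Six 101-point channels on the percent-of-movement grid, plus labels.

    Position channels are dimensionless (fraction of body height, baseline
    subtracted so they start at exactly 0), velocity channels are body
    heights per second, GRF channels are N/kg.
    """

    channels: dict[str, np.ndarray]
    participant_id: int
    condition: str
    trial_index: int
    start_time_s: float
    catch_time_s: float
    peak_time_s: float
    body_height: float
    body_mass: float

    @property
    def key(self) -> str:
        return f"P{self.participant_id:02d}_{self.condition}_T{self.trial_index}"


def barbell_centre(marker_left: np.ndarray, marker_right: np.ndarray) -> np.ndarray:
    """Element-wise mean of the two barbell-end marker series."""
    left = np.asarray(marker_left, dtype=float)
    right = np.asarray(marker_right, dtype=float)
    if left.shape != right.shape:
        raise ValueError(f"marker shapes differ: {left.shape} vs {right.shape}")
    return 0.5 * (left + right)


def total_grf(plate1: np.ndarray, plate2: np.ndarray) -> np.ndarray:
    """Element-wise vector sum of the two force-plate series."""
    p1 = np.asarray(plate1, dtype=float)
    p2 = np.asarray(plate2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError(f"plate shapes differ: {p1.shape} vs {p2.shape}")
    return p1 + p2


def lowpass(x: np.ndarray, fs: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along axis 0.

    Two passes of an ``order``-th-order filter: unit DC gain, squared
    magnitude response (amplitude ratio 1/2 at the cutoff frequency), no
    phase distortion.
    """
    x = np.asarray(x, dtype=float)
    if cutoff_hz >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {fs / 2} Hz")
    if x.shape[0] <= 3 * order:
        raise ValueError("series too short for zero-phase filtering")
    sos = _signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, x, axis=0)


def differentiate(position: np.ndarray, fs: float) -> np.ndarray:
    """Numerical time derivative: central differences inside, one-sided at the ends.

    Exact for linear signals everywhere; second-order accurate in the
    interior.
    """
    position = np.asarray(position, dtype=float)
    if position.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(position, 1.0 / fs, axis=0)


def segment_trial(velocity_v: np.ndarray, position_v: np.ndarray,
                  fs: float) -> tuple[int, int]:
    """Locate the start and catch events on the vertical channels.

    start: first sample with vertical velocity >= 0.01 m/s.
    catch: after the maximum vertical displacement, find the first sample of
    the negative-velocity phase, then the first subsequent sample with
    velocity >= 0.

    Raises :class:`SegmentationError` when either event does not exist.
    """
    v = np.asarray(velocity_v, dtype=float)
    z = np.asarray(position_v, dtype=float)
    if v.shape != z.shape or v.ndim != 1:
        raise ValueError("velocity_v and position_v must be aligned 1-D series")

    above = np.nonzero(v >= START_VELOCITY_THRESHOLD)[0]
    if above.size == 0:
        raise SegmentationError("no sample reaches the start velocity threshold")
    start = int(above[0])

    i_max = int(np.argmax(z))
    neg = np.nonzero(v[i_max + 1:] < 0.0)[0]
    if neg.size == 0:
        raise SegmentationError("no negative-velocity phase after maximum displacement")
    i_neg = i_max + 1 + int(neg[0])

    nonneg = np.nonzero(v[i_neg:] >= 0.0)[0]
    if nonneg.size == 0:
        raise SegmentationError("vertical velocity never returns to zero before the series ends")
    catch = i_neg + int(nonneg[0])

    if start >= catch:
        raise SegmentationError("start event does not precede the catch event")
    return start, catch


def _resample101(x: np.ndarray) -> np.ndarray:
    """Linear resampling of a trimmed channel onto the uniform 0-100% grid."""
    src = np.linspace(0.0, 1.0, x.shape[0])
    dst = np.linspace(0.0, 1.0, N_POINTS)
    return np.interp(dst, src, x)


def normalize_and_trim(position: np.ndarray, velocity: np.ndarray,
                       grf: np.ndarray, start: int, catch: int,
                       marker_fs: float, force_fs: float,
                       body_height: float, body_mass: float) -> dict[str, np.ndarray]:
    """Trim to [start, catch], normalize by body size, resample to 101 points.

    ``position``/``velocity`` are (n, 3) filtered marker-grid series in m and
    m/s; ``grf`` is the (m, 3) filtered total GRF in N.  GRF trimming maps
    the event times onto the force-sample grid by nearest index.  Position
    and velocity are divided by body height, GRF by body mass; afterwards
    the value at point 0 is subtracted from both position channels.
    """
    if body_height <= 0 or body_mass <= 0:
        raise ValueError("body_height and body_mass must be positive")
    pos = position[start:catch + 1]
    vel = velocity[start:catch + 1]
    i0 = int(round(start / marker_fs * force_fs))
    i1 = int(round(catch / marker_fs * force_fs))
    i0 = min(max(i0, 0), grf.shape[0] - 2)
    i1 = min(max(i1, i0 + 1), grf.shape[0] - 1)
    force = grf[i0:i1 + 1]

    channels = {
        "position.AP": _resample101(pos[:, _AP]) / body_height,
        "position.V": _resample101(pos[:, _V]) / body_height,
        "velocity.AP": _resample101(vel[:, _AP]) / body_height,
        "velocity.V": _resample101(vel[:, _V]) / body_height,
        "GRF.AP": _resample101(force[:, _AP]) / body_mass,
        "GRF.V": _resample101(force[:, _V]) / body_mass,
    }
    for name in ("position.AP", "position.V"):
        channels[name] = channels[name] - channels[name][0]
    return channels


def process_trial(raw, spec: FilterSpec = FilterSpec()) -> ProcessedTrial:
    """Run the full preprocessing chain on one raw trial.

    ``raw`` is any object with the :class:`~liftsig.synthgen.RawTrial`
    attributes, so directories of real recordings matching the same contract
    can be dropped in.
    """
    centre = barbell_centre(raw.marker_left, raw.marker_right)
    pos_f = lowpass(centre, raw.marker_fs, spec.cutoff_position_hz, spec.order)
    vel = differentiate(pos_f, raw.marker_fs)
    start, catch = segment_trial(vel[:, _V], pos_f[:, _V], raw.marker_fs)
    i_peak = start + int(np.argmax(pos_f[start:catch + 1, _V]))

    grf = total_grf(raw.grf_plate1, raw.grf_plate2)
    grf_f = lowpass(grf, raw.force_fs, spec.cutoff_grf_hz, spec.order)

    channels = normalize_and_trim(pos_f, vel, grf_f, start, catch,
                                  raw.marker_fs, raw.force_fs,
                                  raw.body_height, raw.body_mass)
    return ProcessedTrial(
        channels=channels,
        participant_id=raw.participant_id,
        condition=raw.condition,
        trial_index=raw.trial_index,
        start_time_s=start / raw.marker_fs,
        catch_time_s=catch / raw.marker_fs,
        peak_time_s=i_peak / raw.marker_fs,
        body_height=raw.body_height,
        body_mass=raw.body_mass,
    )


def process_dataset(raws, spec: FilterSpec = FilterSpec()):
    """Process a list of raw trials, excluding unsegmentable ones.

    Returns ``(processed, exclusions)`` where ``exclusions`` is a list of
    ``(trial_key, reason)`` pairs; retained + excluded always equals the raw
    count.
    """
    processed: list[ProcessedTrial] = []
    exclusions: list[tuple[str, str]] = []
    for raw in raws:
        try:
            processed.append(process_trial(raw, spec))
        except SegmentationError as err:
            key = getattr(raw, "key", repr(raw))
            exclusions.append((key, str(err)))
            log.warning("excluded trial %s: %s", key, err)
    return processed, exclusions
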
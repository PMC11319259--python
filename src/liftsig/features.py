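"""Feature assembly and scaling for the SVM classification tasks.

An input combination selects an ordered subset of the six processed channels;
each trial's selected channels are concatenated into one row of a feature
matrix (101 points per channel).  Three scaling approaches are supported:
none, batch (divide each channel by its maximum absolute value over the
*training* trials), and instance (divide each trial's channel by that trial's
own maximum absolute value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import CHANNELS, N_POINTS, ProcessedTrial
from .synthgen import CONDITIONS

__all__ = [
    "SCALINGS",
    "InputCombo",
    "FeatureMatrix",
    "combo_registry",
    "get_combo",
    "assemble",
    "scale",
    "batch_factors",
]

SCALINGS = ("none", "batch", "instance")


@dataclass(frozen=True)
class InputCombo:
    """A named, ordered subset of the processed channels."""

    name: str
    channels: tuple[str, ...]
    kind: str  # "kinematic" | "kinetic" | "mixed"

    def __post_init__(self):
        if not self.channels:
            raise ValueError("combo must select at least one channel")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")


_REGISTRY = (
    # 9 kinematic-only combinations
    InputCombo("Position.AP", ("position.AP",), "kinematic"),
    InputCombo("Position.V", ("position.V",), "kinematic"),
    InputCombo("Position.AP, Position.V", ("position.AP", "position.V"), "kinematic"),
    InputCombo("Velocity.AP", ("velocity.AP",), "kinematic"),
    InputCombo("Velocity.V", ("velocity.V",), "kinematic"),
    InputCombo("Velocity.AP, Velocity.V", ("velocity.AP", "velocity.V"), "kinematic"),
    InputCombo("Position.AP, Velocity.AP", ("position.AP", "velocity.AP"), "kinematic"),
    InputCombo("Position.V, Velocity.V", ("position.V", "velocity.V"), "kinematic"),
    InputCombo("Position.AP, Position.V, Velocity.AP, Velocity.V",
               ("position.AP", "position.V", "velocity.AP", "velocity.V"), "kinematic"),
    # 3 kinetic-only combinations
    InputCombo("GRF.AP", ("GRF.AP",), "kinetic"),
    InputCombo("GRF.V", ("GRF.V",), "kinetic"),
    InputCombo("GRF.AP, GRF.V", ("GRF.AP", "GRF.V"), "kinetic"),
    # 3 mixed combinations
    InputCombo("Position.AP, Velocity.AP, GRF.AP",
               ("position.AP", "velocity.AP", "GRF.AP"), "mixed"),
    InputCombo("Position.V, Velocity.V, GRF.V",
               ("position.V", "velocity.V", "GRF.V"), "mixed"),
    InputCombo("All", CHANNELS, "mixed"),
)


def combo_registry() -> list[InputCombo]:
    """The 15 input combinations, in reporting order (9 kinematic, 3 kinetic, 3 mixed)."""
    return list(_REGISTRY)


def get_combo(name: str) -> InputCombo:
    """Look an input combination up by its reporting name."""
    for combo in _REGISTRY:
        if combo.name == name:
            return combo
    raise KeyError(f"unknown input combination {name!r}")


@dataclass
class FeatureMatrix:
    """Trials-by-features matrix with aligned row labels.

    Columns are consecutive 101-point channel blocks in the combination's
    channel order.
    """

    X: np.ndarray
    combo: InputCombo
    participants: np.ndarray
    conditions: np.ndarray
    trial_indices: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def block(self, channel: str) -> slice:
        """Column slice of one channel's block."""
        i = self.combo.channels.index(channel)
        return slice(i * N_POINTS, (i + 1) * N_POINTS)

    def rows(self, idx: np.ndarray) -> "FeatureMatrix":
        """Row-subset view (copy) preserving labels."""
        return FeatureMatrix(self.X[idx], self.combo, self.participants[idx],
                             self.conditions[idx], self.trial_indices[idx])


def _sort_key(trial: ProcessedTrial):
    return (trial.participant_id, CONDITIONS.index(trial.condition), trial.trial_index)


def assemble(trials: list[ProcessedTrial], combo: InputCombo | str) -> FeatureMatrix:
    """Concatenate each trial's selected channels into a feature matrix.

    Rows are deterministically ordered by (participant, condition,
    trial index); columns follow the combination's channel order.
    """
    if isinstance(combo, str):
        combo = get_combo(combo)
    ordered = sorted(trials, key=_sort_key)
    rows = []
    for trial in ordered:
        missing = [c for c in combo.channels if c not in trial.channels]
        if missing:
            raise ValueError(f"trial {trial.key} lacks channels {missing}")
        rows.append(np.concatenate([trial.channels[c] for c in combo.channels]))
    return FeatureMatrix(
        X=np.array(rows),
        combo=combo,
        participants=np.array([t.participant_id for t in ordered]),
        conditions=np.array([t.condition for t in ordered]),
        trial_indices=np.array([t.trial_index for t in ordered]),
    )


def batch_factors(train: FeatureMatrix) -> np.ndarray:
    """Per-channel max-abs statistics of the training matrix (zero -> 1 guard)."""
    factors = np.empty(len(train.combo.channels))
    for i, ch in enumerate(train.combo.channels):
        m = np.max(np.abs(train.X[:, train.block(ch)]))
        factors[i] = m if m > 0 else 1.0
    return factors


def scale(train: FeatureMatrix, test: FeatureMatrix,
          approach: str) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Apply one of the three scaling approaches; never across channels.

    batch: both matrices are divided channel-wise by the training set's
    max-abs per channel (the test set never contributes a statistic).
    instance: each row's channel block is divided by that row's own channel
    max-abs.  All-zero channels are left unchanged.
    """
    if train.combo.channels != test.combo.channels:
        raise ValueError("train and test matrices have different column structure")
    if approach == "none":
        return train, test
    Xtr = train.X.copy()
    Xte = test.X.copy()
    if approach == "batch":
        factors = batch_factors(train)
        for i, ch in enumerate(train.combo.channels):
            blk = train.block(ch)
            Xtr[:, blk] /= factors[i]
            Xte[:, blk] /= factors[i]
    elif approach == "instance":
        for X in (Xtr, Xte):
            for ch in train.combo.channels:
                blk = train.block(ch)
                m = np.max(np.abs(X[:, blk]), axis=1, keepdims=True)
                m[m == 0] = 1.0
                X[:, blk] /= m
    else:
        raise ValueError(f"unknown scaling approach {approach!r}; expected one of {SCALINGS}")
    tr = FeatureMatrix(Xtr, train.combo, train.participants, train.conditions,
                       train.trial_indices)
    te = FeatureMatrix(Xte, test.combo, test.participants, test.conditions,
                       test.trial_indices)
    return tr, te
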
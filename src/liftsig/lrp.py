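"""Layer-wise relevance propagation for the trained linear SVMs.

For a linear model the decision score of the ground-truth class c decomposes
exactly into per-feature contributions R_i = W_c,i * x_i (the bias receives
no relevance), so the conservation identity sum_i R_i = W_c . x holds to
machine precision.  Following the explainability protocol used for
participant classification, only positive relevances (those supporting the
true class) are kept, normalized per trial to that trial's maximum positive
relevance, and averaged across all test trials of all cross-validation folds
to yield a model-level profile alongside the mean +/- SD of the (scaled)
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import LinearModel, _task_labels, plan_folds, predict, train
from .features import FeatureMatrix, InputCombo, assemble, scale
from .preprocess import N_POINTS, ProcessedTrial

__all__ = [
    "TrialRelevance",
    "RelevanceProfile",
    "decompose",
    "aggregate",
    "relevance_profile",
    "profile_to_frame",
]


@dataclass
class TrialRelevance:
    """Per-feature relevance of one trial's ground-truth decision score."""

    trial_id: str
    relevance: np.ndarray   # signed, same layout as the feature vector
    normalized: np.ndarray  # positive part / max positive relevance, in [0, 1]


@dataclass
class RelevanceProfile:
    """Aggregated relevance and matching input statistics per channel.

    Arrays have shape (n_channels, 101); rows follow ``channels``.
    """

    channels: tuple[str, ...]
    mean_relevance: np.ndarray
    mean_input: np.ndarray
    sd_input: np.ndarray
    n_trials: int

    def channel_mass(self, channel: str) -> float:
        """Summed mean relevance of one channel (its share of the profile)."""
        return float(self.mean_relevance[self.channels.index(channel)].sum())


def decompose(model: LinearModel, x: np.ndarray, true_class,
              trial_id: str = "") -> TrialRelevance:
    """Decompose the ground-truth-class decision score of one input.

    ``relevance_i = W_c,i * x_i``; the normalized vector keeps only positive
    relevances divided by the trial's maximum positive relevance (all zeros
    when no positive relevance exists).
    """
    x = np.asarray(x, dtype=float).ravel()
    matches = np.nonzero(model.classes == true_class)[0]
    if matches.size == 0:
        raise ValueError(f"class {true_class!r} not among model classes")
    c = int(matches[0])
    if x.shape[0] != model.W.shape[1]:
        raise ValueError("input dimension does not match model")
    relevance = model.W[c] * x
    positive = np.clip(relevance, 0.0, None)
    peak = positive.max() if positive.size else 0.0
    normalized = positive / peak if peak > 0 else np.zeros_like(positive)
    return TrialRelevance(trial_id=trial_id, relevance=relevance,
                          normalized=normalized)


def aggregate(per_trial: list[TrialRelevance], inputs: np.ndarray,
              combo: InputCombo) -> RelevanceProfile:
    """Average normalized relevances and input statistics over trials.

    ``inputs`` holds the (scaled) feature vectors the relevances were
    computed on, one row per entry of ``per_trial``.  The result is
    invariant under trial ordering.
    """
    if not per_trial:
        raise ValueError("no trial relevances to aggregate")
    R = np.array([tr.normalized for tr in per_trial])
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if R.shape != inputs.shape:
        raise ValueError("relevance and input layouts differ")
    k = len(combo.channels)
    if R.shape[1] != k * N_POINTS:
        raise ValueError("feature layout does not match the combo")
    mean_r = R.mean(axis=0).reshape(k, N_POINTS)
    mean_x = inputs.mean(axis=0).reshape(k, N_POINTS)
    sd_x = inputs.std(axis=0, ddof=1 if inputs.shape[0] > 1 else 0).reshape(k, N_POINTS)
    return RelevanceProfile(channels=tuple(combo.channels), mean_relevance=mean_r,
                            mean_input=mean_x, sd_input=sd_x,
                            n_trials=len(per_trial))


def relevance_profile(trials: list[ProcessedTrial], combo: InputCombo | str,
                      scaling: str, task: str = "participant", C: float = 1.0,
                      group_map: list[list[int]] | None = None) -> RelevanceProfile:
    """Model-level relevance profile over all test trials of all folds.

    Re-runs the cross-validation of :func:`liftsig.classify.run_experiment`
    for one combo and scaling, decomposes every test trial with respect to
    its ground-truth class, and aggregates.  Relevances are computed on the
    scaled inputs actually fed to the SVM, so scaling sensitivity is
    propagated into the profile.
    """
    fm = assemble(trials, combo)
    plan = plan_folds(fm.participants, fm.conditions, task, group_map)
    y = _task_labels(fm, task)

    per_trial: list[TrialRelevance] = []
    rows = []
    for fold in plan.folds:
        tr, te = scale(fm.rows(fold.train_idx), fm.rows(fold.test_idx), scaling)
        model = train(tr.X, y[fold.train_idx], C=C)
        for i, row in enumerate(fold.test_idx):
            x = te.X[i]
            per_trial.append(decompose(model, x, y[row],
                                       trial_id=f"{fold.held_out}:{row}"))
            rows.append(x)
    return aggregate(per_trial, np.array(rows), fm.combo)


def profile_to_frame(profile: RelevanceProfile):
    """Long-format table: channel, percent of movement, input stats, relevance."""
    import pandas as pd

    records = []
    pct = np.linspace(0, 100, N_POINTS)
    for i, ch in enumerate(profile.channels):
        for j in range(N_POINTS):
            records.append({
                "channel": ch,
                "percent": pct[j],
                "mean_input": profile.mean_input[i, j],
                "sd_input": profile.sd_input[i, j],
                "mean_relevance": profile.mean_relevance[i, j],
            })
    return pd.DataFrame.from_records(records)
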
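"""Linear-SVM classification under leave-one-group-out cross-validation.

Two tasks are supported on the same trials:

* ``participant`` — who lifted: 15-way classification, 4 folds each holding
  out all trials of one motor-learning condition (tested in the order bCIL,
  sCIL, DL, RL).
* ``model`` — which motor-learning condition preceded the trial: 4-way
  classification, 5 folds each holding out a fixed group of 3 participants.

The classifier is a one-vs-rest linear SVM with L2 regularization and
squared-hinge loss, C = 1, no tuning (liblinear via scikit-learn).  Accuracy
is reported per fold and scaling approach; the headline "averaged accuracy"
is the arithmetic mean over all fold x scaling values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .features import SCALINGS, FeatureMatrix, InputCombo, assemble, scale
from .preprocess import ProcessedTrial
from .synthgen import CONDITIONS

__all__ = [
    "TASKS",
    "FOLD_CONDITION_ORDER",
    "Fold",
    "FoldPlan",
    "LinearModel",
    "AccuracyReport",
    "plan_folds",
    "train",
    "predict",
    "run_experiment",
    "zero_rule_accuracy",
]

TASKS = ("participant", "model")

#: Condition tested per fold of the participant task, in fold order.
FOLD_CONDITION_ORDER = ("bCIL", "sCIL", "DL", "RL")

GROUP_SIZE = 3  # participants per held-out group in the model task


@dataclass(frozen=True)
class Fold:
    train_idx: np.ndarray
    test_idx: np.ndarray
    held_out: str


@dataclass(frozen=True)
class FoldPlan:
    task: str
    folds: tuple[Fold, ...]


@dataclass
class LinearModel:
    """One-vs-rest linear SVM: per-class weight vectors and biases.

    The decision score of class ``c`` at input ``x`` is ``W[c] @ x + b[c]``.
    """

    classes: np.ndarray
    W: np.ndarray  # (n_classes, n_features)
    b: np.ndarray  # (n_classes,)
    C: float = 1.0


def plan_folds(participants: np.ndarray, conditions: np.ndarray, task: str,
               group_map: list[list[int]] | None = None) -> FoldPlan:
    """Partition trial indices into leave-one-group-out folds for one task.

    ``participants`` and ``conditions`` are the aligned row labels of a
    feature matrix.  For the model task, participants are chunked into
    groups of 3 in sorted order unless an explicit ``group_map`` (list of
    participant-id lists) is supplied; a participant count not divisible by
    3 requires the explicit map.
    """
    participants = np.asarray(participants)
    conditions = np.asarray(conditions)
    if participants.shape != conditions.shape:
        raise ValueError("participants and conditions must be aligned")
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    n = participants.shape[0]
    all_idx = np.arange(n)

    folds = []
    if task == "participant":
        for cond in FOLD_CONDITION_ORDER:
            test = all_idx[conditions == cond]
            if test.size == 0:
                raise ValueError(f"no trials labelled with condition {cond!r}")
            folds.append(Fold(all_idx[conditions != cond], test, cond))
    else:
        unique = sorted(set(int(p) for p in participants))
        if group_map is None:
            if len(unique) % GROUP_SIZE != 0:
                raise ValueError(
                    f"{len(unique)} participants are not divisible into groups of "
                    f"{GROUP_SIZE}; supply an explicit group_map")
            group_map = [unique[i:i + GROUP_SIZE]
                         for i in range(0, len(unique), GROUP_SIZE)]
        else:
            flat = [p for g in group_map for p in g]
            if sorted(flat) != unique:
                raise ValueError("group_map must partition the participant ids exactly")
        for group in group_map:
            mask = np.isin(participants, group)
            folds.append(Fold(all_idx[~mask], all_idx[mask],
                              ",".join(str(p) for p in group)))
    for f in folds:
        assert np.intersect1d(f.train_idx, f.test_idx).size == 0
    return FoldPlan(task=task, folds=tuple(folds))


def train(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> LinearModel:
    """Fit a one-vs-rest linear SVM (L2 penalty, squared-hinge loss).

    Deterministic: fixed tolerance 1e-4, fixed data order, pinned internal
    seed.  No centering or scaling is applied here.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires at least 2 classes")
    if X.shape[0] < classes.size:
        raise ValueError("fewer rows than classes")
    clf = LinearSVC(C=C, penalty="l2", loss="squared_hinge", dual="auto",
                    tol=1e-4, max_iter=20000, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    if classes.size == 2:
        # liblinear fits a single separating function for two classes; expand
        # to the per-class convention (argmax then equals the sign rule).
        w = clf.coef_[0]
        b = float(clf.intercept_[0])
        W = np.vstack([-w, w])
        bias = np.array([-b, b])
    else:
        W = clf.coef_.copy()
        bias = clf.intercept_.copy()
    return LinearModel(classes=clf.classes_.copy(), W=W, b=bias, C=C)


def decision_scores(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Per-class decision scores W_c @ x + b_c for every row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.W.shape[1]:
        raise ValueError(f"feature count {X.shape[1]} does not match model "
                         f"({model.W.shape[1]})")
    return X @ model.W.T + model.b


def predict(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Argmax over class decision scores; ties go to the lowest class index."""
    scores = decision_scores(model, X)
    return model.classes[np.argmax(scores, axis=1)]


@dataclass
class AccuracyReport:
    """Per-fold, per-scaling accuracies and their aggregates for one combo."""

    task: str
    combo_name: str
    scalings: tuple[str, ...]
    fold_labels: tuple[str, ...]
    accuracies: dict[str, np.ndarray]          # scaling -> per-fold accuracy, %
    correct: dict[str, np.ndarray]             # scaling -> per-fold correct counts
    test_sizes: np.ndarray                     # per-fold test-set sizes

    def scaling_mean_sd(self, scaling: str) -> tuple[float, float]:
        a = self.accuracies[scaling]
        return float(np.mean(a)), float(np.std(a, ddof=1))

    @property
    def all_values(self) -> np.ndarray:
        """All fold x scaling accuracy values (12 or 15 on the full design)."""
        return np.concatenate([self.accuracies[s] for s in self.scalings])

    @property
    def averaged_accuracy(self) -> float:
        """Arithmetic mean over every fold x scaling value."""
        return float(np.mean(self.all_values))

    @property
    def averaged_sd(self) -> float:
        return float(np.std(self.all_values, ddof=1))


def _task_labels(fm: FeatureMatrix, task: str) -> np.ndarray:
    return fm.participants if task == "participant" else fm.conditions


def run_experiment(trials: list[ProcessedTrial], task: str,
                   combo: InputCombo | str, scalings="all", C: float = 1.0,
                   group_map: list[list[int]] | None = None,
                   collect_predictions: bool = False):
    """Cross-validated accuracy of one input combination on one task.

    Per fold and scaling approach: scale (batch statistics from the training
    split only), fit, and evaluate test accuracy as correct/total x 100.
    Returns an :class:`AccuracyReport`; with ``collect_predictions`` also a
    list of per-trial prediction records.
    """
    if scalings == "all":
        scalings = SCALINGS
    elif isinstance(scalings, str):
        scalings = (scalings,)
    else:
        scalings = tuple(scalings)
    for s in scalings:
        if s not in SCALINGS:
            raise ValueError(f"unknown scaling {s!r}")

    fm = assemble(trials, combo)
    plan = plan_folds(fm.participants, fm.conditions, task, group_map)
    y = _task_labels(fm, task)

    accuracies = {s: np.empty(len(plan.folds)) for s in scalings}
    correct = {s: np.empty(len(plan.folds), dtype=int) for s in scalings}
    predictions = []
    for s in scalings:
        for k, fold in enumerate(plan.folds):
            tr, te = scale(fm.rows(fold.train_idx), fm.rows(fold.test_idx), s)
            model = train(tr.X, y[fold.train_idx], C=C)
            pred = predict(model, te.X)
            truth = y[fold.test_idx]
            n_ok = int(np.sum(pred == truth))
            correct[s][k] = n_ok
            accuracies[s][k] = 100.0 * n_ok / truth.size
            if collect_predictions:
                for i, row in enumerate(fold.test_idx):
                    predictions.append({
                        "participant_id": int(fm.participants[row]),
                        "condition": str(fm.conditions[row]),
                        "trial_index": int(fm.trial_indices[row]),
                        "scaling": s, "fold": fold.held_out,
                        "true": str(truth[i]), "predicted": str(pred[i]),
                    })

    report = AccuracyReport(
        task=task, combo_name=fm.combo.name, scalings=scalings,
        fold_labels=tuple(f.held_out for f in plan.folds),
        accuracies=accuracies, correct=correct,
        test_sizes=np.array([f.test_idx.size for f in plan.folds]),
    )
    if collect_predictions:
        return report, predictions
    return report


def zero_rule_accuracy(trials: list[ProcessedTrial], task: str,
                       group_map: list[list[int]] | None = None) -> float:
    """Majority-class baseline accuracy (%) under the same fold plan.

    Ties among training-class frequencies go to the lowest label.  On the
    balanced full design this is 100/15 = 6.7% for the participant task and
    exactly 25% for the model task.
    """
    fm = assemble(trials, "Position.V")  # labels only; channel choice irrelevant
    plan = plan_folds(fm.participants, fm.conditions, task, group_map)
    y = _task_labels(fm, task)
    accs = []
    for fold in plan.folds:
        labels, counts = np.unique(y[fold.train_idx], return_counts=True)
        majority = labels[np.argmax(counts)]
        accs.append(100.0 * np.mean(y[fold.test_idx] == majority))
    return float(np.mean(accs))
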
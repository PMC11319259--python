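"""Fold planning, SVM training/prediction, report consistency, signal recovery."""

import numpy as np
import pytest
from sklearn.svm import LinearSVC

from liftsig.classify import (FOLD_CONDITION_ORDER, LinearModel, plan_folds,
                              predict, run_experiment, train,
                              zero_rule_accuracy)
from liftsig.features import assemble
from liftsig.preprocess import process_dataset
from liftsig.synthgen import GenParams, generate_dataset


def _labels(processed, combo="Position.V"):
    fm = assemble(processed, combo)
    return fm.participants, fm.conditions


class TestFoldPlanning:
    def test_participant_task_folds_on_full_design(self, processed):
        p, c = _labels(processed)
        plan = plan_folds(p, c, "participant")
        assert len(plan.folds) == 4
        assert tuple(f.held_out for f in plan.folds) == FOLD_CONDITION_ORDER
        for f in plan.folds:
            assert f.train_idx.size == 135
            assert f.test_idx.size == 45
        tested = np.sort(np.concatenate([f.test_idx for f in plan.folds]))
        np.testing.assert_array_equal(tested, np.arange(180))

    def test_model_task_folds_on_full_design(self, processed):
        p, c = _labels(processed)
        plan = plan_folds(p, c, "model")
        assert len(plan.folds) == 5
        for f in plan.folds:
            assert f.train_idx.size == 144
            assert f.test_idx.size == 36
            # held-out participants never appear in training
            held = {int(x) for x in f.held_out.split(",")}
            assert held.isdisjoint(set(p[f.train_idx]))
        tested = np.sort(np.concatenate([f.test_idx for f in plan.folds]))
        np.testing.assert_array_equal(tested, np.arange(180))

    def test_tiny_design_counts(self):
        proc, _ = process_dataset(generate_dataset(
            GenParams(seed=3, n_participants=2, n_trials=1)))
        p, c = _labels(proc)
        plan = plan_folds(p, c, "participant")
        assert all(f.train_idx.size == 6 and f.test_idx.size == 2
                   for f in plan.folds)

    def test_indivisible_participants_need_group_map(self, small_processed):
        p, c = _labels(small_processed)  # 6 participants: divisible, fine
        plan = plan_folds(p, c, "model")
        assert len(plan.folds) == 2
        # 6 participants with a non-partition map must fail
        with pytest.raises(ValueError):
            plan_folds(p, c, "model", group_map=[[1, 2], [3]])
        plan2 = plan_folds(p, c, "model", group_map=[[1, 2], [3, 4], [5, 6]])
        assert len(plan2.folds) == 3


class TestTrainPredict:
    def test_separable_clouds_reach_perfect_training_accuracy(self, rng):
        X = np.r_[rng.normal(0, 0.1, (20, 5)) + 5, rng.normal(0, 0.1, (20, 5)) - 5]
        y = np.r_[np.zeros(20), np.ones(20)]
        model = train(X, y)
        assert np.mean(predict(model, X) == y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((5, 2)), np.zeros(5))

    def test_predict_argmax_and_tie_break(self):
        model = LinearModel(classes=np.array([1, 2]),
                            W=np.array([[2.0, 0.0], [-1.0, 0.0]]),
                            b=np.array([0.0, 0.0]))
        assert predict(model, np.array([[1.0, 0.0]]))[0] == 1
        # exact tie: x = 0 gives score 0 for both -> first class
        assert predict(model, np.array([[0.0, 0.0]]))[0] == 1

    def test_binary_predictions_match_sign_rule(self, rng):
        X = rng.normal(size=(60, 8))
        y = (X[:, 0] + 0.2 * rng.normal(size=60) > 0).astype(int)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        model = train(X, y)
        clf = LinearSVC(C=1.0, penalty="l2", loss="squared_hinge", dual="auto",
                        tol=1e-4, max_iter=20000, random_state=0).fit(X, y)
        np.testing.assert_array_equal(predict(model, X), clf.predict(X))

    def test_duplicated_column_weight_split_equivalence(self, rng):
        """Splitting a column's weight across duplicates preserves scores
        exactly; refitting on the duplicated design preserves predictions."""
        X = rng.normal(size=(45, 6))
        y = rng.integers(0, 3, size=45)
        model = train(X, y)
        Xd = np.c_[X, X[:, 0]]
        # weight-mass split: w0 -> (w0/2, w0/2) on the duplicated design
        Wd = np.c_[model.W, model.W[:, 0] / 2]
        Wd[:, 0] /= 2
        split = LinearModel(classes=model.classes, W=Wd, b=model.b)
        from liftsig.classify import decision_scores
        np.testing.assert_allclose(decision_scores(split, Xd),
                                   decision_scores(model, X), atol=1e-6)
        refit = train(Xd, y)
        assert np.mean(predict(refit, Xd) == predict(model, X)) > 0.95


class TestReports:
    def test_report_consistency(self, small_processed):
        rep = run_experiment(small_processed, "participant", "Velocity.V")
        for s in rep.scalings:
            np.testing.assert_allclose(
                rep.accuracies[s],
                100.0 * rep.correct[s] / rep.test_sizes, rtol=1e-12)
            assert np.all((rep.accuracies[s] >= 0) & (rep.accuracies[s] <= 100))
        assert rep.all_values.size == 3 * 4
        assert rep.averaged_accuracy == pytest.approx(np.mean(rep.all_values))

    def test_zero_rule_baselines_on_balanced_design(self, processed):
        assert round(zero_rule_accuracy(processed, "participant"), 1) == 6.7
        assert zero_rule_accuracy(processed, "model") == 25.0

    def test_batch_factors_differ_across_folds(self, small_processed):
        """Leakage guard: each fold's batch statistic comes from its own
        training split, so factors differ between folds."""
        from liftsig.classify import plan_folds as pf
        from liftsig.features import batch_factors

        fm = assemble(small_processed, "GRF.V")
        plan = pf(fm.participants, fm.conditions, "participant")
        factors = [batch_factors(fm.rows(f.train_idx))[0] for f in plan.folds]
        assert len(set(np.round(factors, 12))) > 1


def test_monotone_signal_recovery():
    """Median participant-task accuracy never decreases as individuality grows."""
    medians = []
    for sigma_ind in (0.02, 0.08, 0.16):
        accs = []
        for seed in (0, 1, 2):
            params = GenParams(seed=31 + seed, n_participants=6, n_trials=2,
                               sigma_ind=sigma_ind)
            proc, _ = process_dataset(generate_dataset(params))
            rep = run_experiment(proc, "participant", "All", scalings="batch")
            accs.append(rep.averaged_accuracy)
        medians.append(np.median(accs))
    assert medians[0] <= medians[1] <= medians[2]
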
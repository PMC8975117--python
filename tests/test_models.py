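"""LOSO splitting, the printed-hyperparameter classifiers, the ANN scorer."""

import numpy as np
import pandas as pd
import pytest

from legagility.errors import ValidationError
from legagility.models import (
    AnnScorer,
    ModelSpec,
    TrainConfig,
    fit_ann,
    fit_classifier,
    grid_search,
    loso_splits,
    run_loso,
)


class TestLosoSplits:
    def test_one_fold_per_subject(self):
        folds = loso_splits([f"S{i}" for i in range(5)])
        assert len(folds) == 5
        held = [h for _, h in folds]
        assert sorted(held) == [f"S{i}" for i in range(5)]

    def test_held_out_subject_never_trains(self):
        for train, held in loso_splits(["A", "B", "C"]):
            assert held not in train
            assert len(train) == 2

    def test_both_legs_share_a_fold(self):
        subjects = ["A", "A", "B", "B", "C"]  # per-recording subject ids
        folds = loso_splits(subjects)
        assert len(folds) == 3  # folds per subject, not per recording

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError):
            loso_splits(["only"])


class TestClassifiers:
    def test_svm_separates_separable_toy(self):
        X = np.array([[0.0, 0], [0.1, 0], [0.2, 0.1], [0.1, 0.1],
                      [2.0, 2], [2.1, 2], [2.2, 2.1], [2.0, 2.2]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        model = fit_classifier(ModelSpec("svm"), X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_knn_unanimous_neighbors(self):
        X = np.array([[0.0], [0.1], [0.2], [0.3], [0.4], [5.0]])
        y = np.array([2, 2, 2, 2, 2, 0])
        model = fit_classifier(ModelSpec("knn"), X, y)
        assert model.predict([[0.15]])[0] == 2

    def test_decision_tree_split_budget(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 5))
        y = rng.integers(0, 4, 200)
        model = fit_classifier(ModelSpec("dt"), X, y)
        n_internal = model.tree_.node_count - model.tree_.n_leaves
        assert n_internal <= 4

    def test_default_hyperparameters_are_the_printed_ones(self):
        assert ModelSpec("svm").hyperparameters["box_constraint"] == 36.0
        assert ModelSpec("knn").hyperparameters["n_neighbors"] == 5
        assert ModelSpec("dt").hyperparameters["max_splits"] == 4
        ann = ModelSpec("ann").hyperparameters
        assert (ann["hidden_layers"], ann["hidden_units"]) == (2, 16)
        cfg = TrainConfig()
        assert cfg.max_iterations == 2000
        assert cfg.gradient_floor == 1e-5
        assert cfg.initial_learning_rate == 0.01
        assert (cfg.lr_increase, cfg.lr_decrease) == (1.10, 0.80)


class TestAnnScorer:
    def test_constant_target_is_learned(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 4))
        y = np.full(50, 1.7)
        ann = fit_ann(ModelSpec("ann"), TrainConfig(seed=0), X, y)
        assert np.max(np.abs(ann.predict(X) - 1.7)) < 0.05

    def test_linear_target_capacity(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 2))
        y = 0.8 * X[:, 0] - 0.5 * X[:, 1] + 1.5
        ann = fit_ann(ModelSpec("ann"), TrainConfig(seed=0), X, y)
        rmse = np.sqrt(np.mean((ann.predict(X) - y) ** 2))
        assert rmse < 0.05

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 3))
        y = X[:, 0] + 0.1 * rng.standard_normal(60)
        a = fit_ann(ModelSpec("ann"), TrainConfig(seed=11), X, y)
        b = fit_ann(ModelSpec("ann"), TrainConfig(seed=11), X, y)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_iteration_cap_respected(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 2))
        ann = AnnScorer(2, cfg=TrainConfig(max_iterations=5, seed=0))
        ann.fit(X, rng.standard_normal(30))
        assert ann.n_iterations_ <= 5


def _loso_frame(n_subjects=60, seed=0):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 4, 2 * n_subjects)
    subjects = [f"S{i // 2}" for i in range(2 * n_subjects)]
    X = pd.DataFrame({"f": labels.astype(float)})
    return X, subjects, labels


class TestRunLoso:
    def test_perfect_feature_perfect_knn(self):
        X, subjects, labels = _loso_frame()
        preds = run_loso(ModelSpec("knn"), X, subjects, labels)
        assert np.mean(preds["label"].to_numpy() == labels) == 1.0

    def test_shuffled_labels_hit_chance_level(self):
        rng = np.random.default_rng(5)
        n = 120
        labels = np.tile([0, 1, 2, 3], n // 4)
        subjects = [f"S{i}" for i in range(n)]
        X = pd.DataFrame(rng.standard_normal((n, 4)))
        preds = run_loso(ModelSpec("knn"), X, subjects, labels)
        acc = np.mean(preds["label"].to_numpy() == labels)
        assert abs(acc - 0.25) < 0.1

    def test_ann_labels_are_clipped_rounded_scores(self, recovery_run):
        preds = recovery_run["result"].predictions["ann"]
        cont = preds["continuous_score"].to_numpy(float)
        expected = np.clip(np.sign(cont) * np.floor(np.abs(cont) + 0.5), 0, 3)
        np.testing.assert_array_equal(preds["label"].to_numpy(int),
                                      expected.astype(int))

    def test_fold_ids_group_subjects(self):
        X, subjects, labels = _loso_frame(n_subjects=10)
        preds = run_loso(ModelSpec("dt"), X, subjects, labels)
        frame = preds.assign(subject=subjects)
        # each subject maps to exactly one fold and vice versa
        per_subject = frame.groupby("subject")["fold_id"].nunique()
        assert (per_subject == 1).all()
        per_fold = frame.groupby("fold_id")["subject"].nunique()
        assert (per_fold == 1).all()


class TestGridSearch:
    def test_single_point_grid(self):
        X, subjects, labels = _loso_frame(n_subjects=10)
        only = ModelSpec("knn", {"n_neighbors": 3})
        assert grid_search([only], X, subjects, labels) is only

    def test_recovers_planted_optimal_k(self):
        # tight same-label pairs far apart: k=1 resolves them, k=5 mixes pairs
        rng = np.random.default_rng(6)
        n_pairs = 24
        centers = np.arange(n_pairs) * 10.0
        X = pd.DataFrame({"f": np.repeat(centers, 2) + rng.uniform(0, 0.1, 2 * n_pairs)})
        labels = np.repeat(rng.integers(0, 4, n_pairs), 2)
        subjects = [f"S{i}" for i in range(2 * n_pairs)]  # one recording pair per subject? no: unique
        grid = [ModelSpec("knn", {"n_neighbors": k}) for k in (1, 5)]
        best = grid_search(grid, X, subjects, labels)
        assert best.hyperparameters["n_neighbors"] == 1

    def test_invariant_to_enumeration_order(self):
        X, subjects, labels = _loso_frame(n_subjects=12, seed=7)
        grid = [ModelSpec("knn", {"n_neighbors": k}) for k in (1, 3, 5)]
        a = grid_search(grid, X, subjects, labels)
        b = grid_search(grid[::-1], X, subjects, labels)
        assert a.hyperparameters == b.hyperparameters


def test_recovery_cohort_continuous_scoring(recovery_run):
    """On the balanced synthetic cohort the continuous scorer tracks the
    mean rater score closely and never errs by more than one scale point."""
    result = recovery_run["result"]
    work = result.feature_table[~result.feature_table["excluded"]]
    cont = result.predictions["ann"]["continuous_score"].to_numpy(float)
    mean_scores = work["mean_score"].to_numpy(float)
    r = np.corrcoef(cont, mean_scores)[0, 1]
    err = np.abs(cont - mean_scores)
    assert r >= 0.8
    assert np.mean(err <= 1.0) >= 0.95
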
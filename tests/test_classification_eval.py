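"""Splits, confusion metrics, classifier harness, ablation, CV grid."""

import numpy as np
import pytest

from conect.aco_selection import ACOConfig
from conect.classification_eval import (ConfusionCounts, ModelConfig,
                                        confusion_metrics, cv_grid,
                                        metrics_from_counts, run_ablation,
                                        run_experiment, split_dataset,
                                        train_and_eval)
from tests.conftest import random_feature_table


def dementia_table(seed=0, nsub=8):
    """Separable 3-class table with AD/FTD/HC labels."""
    return random_feature_table(nsub, ("AD", "FTD", "HC"), seed=seed,
                                informative={14: 6.0, 15: 6.0, 3: 4.0})


class TestSplitDataset:
    def test_stratified_record_proportions(self):
        data = random_feature_table(10, ("a", "b", "c"), seed=0)  # 60 rows
        train, test = split_dataset(data, mode="stratified_record",
                                    test_fraction=0.2, seed=1)
        assert len(test) == 12
        counts = {c: test.labels.count(c) for c in "abc"}
        assert all(v == 4 for v in counts.values())

    def test_grouped_subject_no_overlap(self):
        data = dementia_table()
        train, test = split_dataset(data, mode="grouped_subject", seed=1)
        assert set(train.groups).isdisjoint(test.groups)
        assert set(train.labels) == set(test.labels) == {"AD", "FTD", "HC"}

    def test_deterministic_per_seed(self):
        data = dementia_table()
        s1 = split_dataset(data, seed=7)[1].groups
        s2 = split_dataset(data, seed=7)[1].groups
        s3 = split_dataset(data, seed=8)[1].groups
        assert s1 == s2
        assert s1 != s3

    def test_single_subject_class_fails_cleanly(self):
        data = random_feature_table(1, ("a", "b"), seed=0)
        with pytest.raises(ValueError, match="fewer than 2 subjects"):
            split_dataset(data, mode="grouped_subject")

    def test_invalid_arguments(self):
        data = dementia_table()
        with pytest.raises(ValueError):
            split_dataset(data, test_fraction=1.5)
        with pytest.raises(ValueError):
            split_dataset(data, mode="bogus")


class TestConfusionMetrics:
    def test_hand_computed_counts(self):
        m = metrics_from_counts(ConfusionCounts(TP=9, FP=1, TN=8, FN=2))
        assert m["precision"] == pytest.approx(0.9)
        assert m["sensitivity"] == pytest.approx(9 / 11)
        assert m["specificity"] == pytest.approx(8 / 9)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["f1"] == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11))
        assert m["f1"] == pytest.approx(0.857142857, abs=1e-6)

    def test_perfect_prediction(self):
        rep = confusion_metrics(["a", "b", "a"], ["a", "b", "a"],
                                positive_class="a")
        assert (rep.accuracy, rep.sensitivity, rep.specificity,
                rep.precision, rep.f1) == (1, 1, 1, 1, 1)

    def test_f1_identity_holds_per_class(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(list("abc"), size=60)
        y_pred = rng.choice(list("abc"), size=60)
        rep = confusion_metrics(y_true, y_pred)
        for cls, m in rep.per_class.items():
            if m["precision"] + m["sensitivity"] > 0:
                assert m["f1"] == pytest.approx(
                    2 * m["precision"] * m["sensitivity"]
                    / (m["precision"] + m["sensitivity"]))

    def test_macro_average_matches_sklearn(self):
        from sklearn.metrics import precision_score, recall_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            y_true = rng.choice(list("abc"), size=40)
            y_pred = rng.choice(list("abc"), size=40)
            rep = confusion_metrics(y_true, y_pred)
            assert rep.sensitivity == pytest.approx(
                recall_score(y_true, y_pred, average="macro"))
            assert rep.precision == pytest.approx(
                precision_score(y_true, y_pred, average="macro",
                                zero_division=0))

    def test_zero_denominator_reports_zero(self):
        rep = confusion_metrics(["a", "a"], ["b", "b"], positive_class="b")
        assert rep.precision == 0.0  # TP=0, FP=2 -> 0/2; sens 0/0 -> 0
        assert rep.sensitivity == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])


class TestTrainAndEval:
    @pytest.mark.parametrize("kind", ["random_forest", "adaboost",
                                      "bagged_trees", "knn", "rbf_svm"])
    def test_all_models_learn_separable_data(self, kind):
        data = dementia_table(seed=2)
        train, test = split_dataset(data, seed=1)
        model = ModelConfig(kind=kind, trees=50, seed=0)
        rep = train_and_eval(train, test, model)
        assert rep.accuracy >= 0.8

    def test_permuted_labels_fall_to_chance(self):
        accs = []
        for seed in range(10):
            data = dementia_table(seed=seed)
            rng = np.random.default_rng(seed)
            data.labels = list(rng.permutation(data.labels))
            train, test = split_dataset(data, mode="stratified_record",
                                        seed=seed)
            rep = train_and_eval(train, test,
                                 ModelConfig(trees=50, seed=seed))
            accs.append(rep.accuracy)
        assert 0.2 <= np.mean(accs) <= 0.47

    def test_deterministic(self):
        data = dementia_table(seed=3)
        train, test = split_dataset(data, seed=2)
        m = ModelConfig(trees=50, seed=5)
        r1 = train_and_eval(train, test, m)
        r2 = train_and_eval(train, test, m)
        assert r1.as_dict() == r2.as_dict()

    def test_single_class_training_rejected(self):
        data = dementia_table().filter_classes(["AD"])
        with pytest.raises(ValueError):
            train_and_eval(data, data, ModelConfig())


class TestRunExperiment:
    def test_binary_task_filters_classes(self):
        data = dementia_table(seed=4)
        rep = run_experiment(data, task="AD_HC", model=ModelConfig(trees=50),
                             seed=1)
        assert set(rep.per_class) <= {"AD", "HC"}

    def test_aco_respects_subset_size_range(self):
        data = dementia_table(seed=5)
        cfg = ACOConfig(n_ants=4, n_iterations=2, fitness_folds=3,
                        fitness_trees=25, seed=0)
        rep = run_experiment(data, task="AD_FTD_HC", use_aco=True,
                             model=ModelConfig(trees=50), seed=1,
                             aco_config=cfg)
        assert 4 <= rep.n_features <= 8
        assert rep.selected == sorted(rep.selected)

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            run_experiment(dementia_table(), task="AD_vs_everyone")

    def test_selection_ignores_test_labels(self):
        """Shuffling held-out labels must not change the selected subset:
        the wrapper runs on the training side only."""
        from conect.aco_selection import run_aco

        data = dementia_table(seed=6)
        train, test = split_dataset(data, seed=2)
        cfg = ACOConfig(n_ants=4, n_iterations=2, fitness_folds=3,
                        fitness_trees=25, seed=3)
        before = run_aco(train, cfg).selected
        rng = np.random.default_rng(0)
        test.labels = list(rng.permutation(test.labels))
        after = run_aco(train, cfg).selected
        assert before == after


class TestAblationAndGrid:
    def test_ablation_shape_and_masking(self):
        data = dementia_table(seed=7)
        cfg = ACOConfig(n_ants=3, n_iterations=2, fitness_folds=3,
                        fitness_trees=25, seed=0)
        table = run_ablation(data, seed=1, model=ModelConfig(trees=25),
                             aco_config=cfg)
        assert table.shape == (5, 4)
        assert set(table.columns) == {"AD_FTD", "FTD_HC", "AD_HC", "AD_FTD_HC"}
        assert ((table >= 0) & (table <= 1)).all().all()

    def test_baseline_row_ignores_geometric_columns(self):
        """Corrupting features 14-15 must not change the baseline-13 row."""
        data = dementia_table(seed=8)
        cfg = ACOConfig(n_ants=3, n_iterations=1, fitness_folds=3,
                        fitness_trees=25, seed=0)
        t1 = run_ablation(data, seed=1, model=ModelConfig(trees=25),
                          aco_config=cfg)
        data.X["feat_14"] = 0.0
        data.X["feat_15"] = 0.0
        t2 = run_ablation(data, seed=1, model=ModelConfig(trees=25),
                          aco_config=cfg)
        assert (t1.loc["baseline13"] == t2.loc["baseline13"]).all()

    def test_cv_grid_shape_bounds_determinism(self):
        data = dementia_table(seed=9)
        g1 = cv_grid(data, trees_list=(25, 50), folds_list=(2, 3), seed=4)
        g2 = cv_grid(data, trees_list=(25, 50), folds_list=(2, 3), seed=4)
        assert g1.shape == (2, 2)
        assert ((g1 >= 0) & (g1 <= 1)).all().all()
        assert g1.equals(g2)
        with pytest.raises(ValueError):
            cv_grid(data, trees_list=(), folds_list=(5,))
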
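"""Classifier harness: splits, metrics, tasks, ablation and the CV grid.

Five classifiers are supported — Random Forest (250 trees by default),
AdaBoost on depth-1 stumps, bagged unpruned trees, k-NN (k = 5) and
RBF-SVM.  Features are z-scored (fit on the training side) for the two
distance/kernel methods only; tree ensembles see raw features.

Metrics follow the standard confusion-table definitions: precision
TP/(TP+FP), sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total and F1 the harmonic mean of precision and sensitivity.  For
multiclass tasks the counts are formed one-vs-rest per class and the four
ratio metrics macro-averaged; accuracy is the overall fraction correct.
Zero-denominator ratios report 0 and log a flag, keeping tables finite.

Two split modes are provided: ``stratified_record`` (row-level,
class-proportion preserving) and ``grouped_subject`` (whole subjects on
one side, approximately stratified).  ``grouped_subject`` is the default
everywhere, so no subject identity leaks across the train/test boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                              RandomForestClassifier)
from sklearn.model_selection import StratifiedGroupKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .aco_selection import ACOConfig, run_aco
from .dataset import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ModelConfig",
    "TASKS",
    "split_dataset",
    "confusion_metrics",
    "train_and_eval",
    "run_experiment",
    "run_ablation",
    "cv_grid",
]

#: classification tasks -> class rosters (None = all three)
TASKS: dict[str, tuple[str, ...] | None] = {
    "AD_FTD_HC": None,
    "AD_HC": ("AD", "HC"),
    "AD_FTD": ("AD", "FTD"),
    "FTD_HC": ("FTD", "HC"),
}


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined (zero denominator); reporting 0", name)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    precision = _ratio(c.TP, c.TP + c.FP, "precision")
    sensitivity = _ratio(c.TP, c.TP + c.FN, "sensitivity")
    specificity = _ratio(c.TN, c.TN + c.FP, "specificity")
    accuracy = _ratio(c.TP + c.TN, c.total, "accuracy")
    f1 = _ratio(2.0 * precision * sensitivity, precision + sensitivity, "f1")
    return {"accuracy": accuracy, "sensitivity": sensitivity,
            "specificity": specificity, "precision": precision, "f1": f1}


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    n_features: int | None = None
    selected: list[int] | None = None
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "f1": self.f1, "per_class": self.per_class,
            "n_features": self.n_features, "selected": self.selected,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ModelConfig:
    """One of the five classifiers with its hyperparameters."""

    kind: str = "random_forest"
    trees: int = 250
    k: int = 5
    C: float = 1.0
    gamma: float | str = "scale"
    seed: int = 0

    def __post_init__(self) -> None:
        kinds = {"random_forest", "adaboost", "bagged_trees", "knn", "rbf_svm"}
        if self.kind not in kinds:
            raise ValueError(f"unknown model kind {self.kind!r}; expected {sorted(kinds)}")
        if self.trees < 1 or self.k < 1:
            raise ValueError("trees and k must be >= 1")

    def make(self):
        if self.kind == "random_forest":
            return RandomForestClassifier(n_estimators=self.trees,
                                          random_state=self.seed, n_jobs=1)
        if self.kind == "adaboost":
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=self.trees, random_state=self.seed)
        if self.kind == "bagged_trees":
            return BaggingClassifier(
                estimator=DecisionTreeClassifier(random_state=self.seed),
                n_estimators=self.trees, random_state=self.seed, n_jobs=1)
        if self.kind == "knn":
            return Pipeline([("scale", StandardScaler()),
                             ("knn", KNeighborsClassifier(n_neighbors=self.k))])
        return Pipeline([("scale", StandardScaler()),
                         ("svm", SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                                     random_state=self.seed))])


def split_dataset(dataset: LabeledDataset, mode: str = "grouped_subject",
                  test_fraction: float = 0.2, seed: int = 1,
                  max_retries: int = 20) -> tuple[LabeledDataset, LabeledDataset]:
    """Train/test split, either row-stratified or whole-subject grouped.

    ``grouped_subject`` assigns each subject entirely to one side while
    preserving class proportions at the subject level (each subject is
    assumed to carry a single class, as in any diagnostic cohort).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = np.asarray(dataset.labels)
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes to split for classification")
    rows = np.arange(len(dataset))

    if mode == "stratified_record":
        train_rows, test_rows = train_test_split(
            rows, test_size=test_fraction, stratify=labels,
            random_state=seed, shuffle=True)
        return dataset.take(sorted(train_rows)), dataset.take(sorted(test_rows))
    if mode != "grouped_subject":
        raise ValueError(f"unknown split mode {mode!r}")

    groups = np.asarray(dataset.groups)
    subj_class: dict[str, str] = {}
    for g, lab in zip(groups, labels):
        subj_class.setdefault(g, lab)
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        test_subjects: set[str] = set()
        ok = True
        for cls in sorted(set(subj_class.values())):
            subs = sorted(s for s, c in subj_class.items() if c == cls)
            if len(subs) < 2:
                ok = False
                break
            n_test = int(round(test_fraction * len(subs)))
            n_test = min(max(n_test, 1), len(subs) - 1)
            test_subjects.update(rng.permutation(subs)[:n_test].tolist())
        if ok:
            test_rows = [r for r in rows if groups[r] in test_subjects]
            train_rows = [r for r in rows if groups[r] not in test_subjects]
            train, test = dataset.take(train_rows), dataset.take(test_rows)
            if set(train.labels) == set(test.labels) == set(labels):
                return train, test
        logger.warning("grouped split attempt %d left a class one-sided; redrawing",
                       attempt + 1)
    raise ValueError("could not produce a grouped split with every class on "
                     "both sides; a class may have fewer than 2 subjects")


def confusion_metrics(y_true: Sequence, y_pred: Sequence,
                      positive_class="macro") -> MetricsReport:
    """Confusion-table metrics; one-vs-rest macro averages for multiclass."""
    y_true = np.asarray([str(v) for v in y_true])
    y_pred = np.asarray([str(v) for v in y_pred])
    if y_true.size == 0:
        raise ValueError("empty label sequences")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")

    def counts(pos: str) -> ConfusionCounts:
        tp = int(np.sum((y_true == pos) & (y_pred == pos)))
        fp = int(np.sum((y_true != pos) & (y_pred == pos)))
        tn = int(np.sum((y_true != pos) & (y_pred != pos)))
        fn = int(np.sum((y_true == pos) & (y_pred != pos)))
        return ConfusionCounts(tp, fp, tn, fn)

    if positive_class != "macro":
        m = metrics_from_counts(counts(str(positive_class)))
        return MetricsReport(**m, per_class={str(positive_class): m})

    classes = sorted(set(y_true) | set(y_pred))
    per_class = {cls: metrics_from_counts(counts(cls)) for cls in classes}
    macro = {k: float(np.mean([per_class[c][k] for c in classes]))
             for k in ("sensitivity", "specificity", "precision", "f1")}
    return MetricsReport(
        accuracy=float(np.mean(y_true == y_pred)),
        sensitivity=macro["sensitivity"], specificity=macro["specificity"],
        precision=macro["precision"], f1=macro["f1"], per_class=per_class,
    )


def train_and_eval(train: LabeledDataset, test: LabeledDataset,
                   model: ModelConfig,
                   subset: Sequence[int] = tuple(range(1, 16))) -> MetricsReport:
    """Fit on the training side, report metrics on the held-out side."""
    subset = sorted(set(int(i) for i in subset))
    if not subset:
        raise ValueError("feature subset must be nonempty")
    if len(set(train.labels)) < 2:
        raise ValueError("training set contains a single class")
    clf = model.make()
    clf.fit(train.columns_for(subset), np.asarray(train.labels))
    y_pred = clf.predict(test.columns_for(subset))
    pos = "macro" if len(set(train.labels)) > 2 else sorted(set(train.labels))[0]
    report = confusion_metrics(test.labels, y_pred, positive_class=pos)
    report.n_features = len(subset)
    report.selected = list(subset)
    report.seed = model.seed
    return report


def run_experiment(dataset: LabeledDataset, task: str = "AD_FTD_HC",
                   use_aco: bool = False,
                   model: ModelConfig = ModelConfig(), seed: int = 1,
                   split_mode: str = "grouped_subject",
                   aco_config: ACOConfig | None = None,
                   subset: Sequence[int] = tuple(range(1, 16))) -> MetricsReport:
    """One task: filter classes, split, optionally select features, evaluate.

    Feature selection (when requested) sees only the training side; the
    held-out test rows never influence the selected subset.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    roster = TASKS[task]
    if roster is not None:
        dataset = dataset.filter_classes(roster)
    missing = ({*(roster or ())} - set(dataset.labels)) if roster else set()
    if missing or len(set(dataset.labels)) < 2:
        raise ValueError(f"dataset lacks the classes required by task {task}")
    train, test = split_dataset(dataset, mode=split_mode, seed=seed)
    subset = sorted(set(int(i) for i in subset))
    if use_aco:
        cfg = aco_config or ACOConfig(seed=seed)
        selection = run_aco(_restrict(train, subset), cfg)
        # selection indices refer to positions in the restricted table
        subset = sorted(subset[i - 1] for i in selection.selected)
    model = replace(model, seed=seed)
    return train_and_eval(train, test, model, subset)


def _restrict(dataset: LabeledDataset, subset: Sequence[int]) -> LabeledDataset:
    """Re-index a feature subset as a contiguous feat_01..feat_0k table."""
    from .dataset import feature_column

    cols = [feature_column(i) for i in subset]
    X = dataset.X[cols].copy()
    X.columns = [feature_column(i) for i in range(1, len(cols) + 1)]
    return LabeledDataset(X=X, labels=list(dataset.labels),
                          groups=list(dataset.groups),
                          channel=list(dataset.channel))


#: ablation rows: configuration name -> 1-based feature indices
ABLATION_CONFIGS: dict[str, list[int]] = {
    "baseline13": list(range(1, 14)),
    "baseline13+WAII": list(range(1, 14)) + [14],
    "baseline13+CBEFI": list(range(1, 14)) + [15],
    "baseline13+WAII+CBEFI": list(range(1, 16)),
    "baseline13+WAII+CBEFI+ACO": list(range(1, 16)),
}


def run_ablation(dataset: LabeledDataset, seed: int = 1,
                 model: ModelConfig = ModelConfig(),
                 aco_config: ACOConfig | None = None,
                 tasks: Sequence[str] = ("AD_FTD", "FTD_HC", "AD_HC",
                                         "AD_FTD_HC"),
                 split_mode: str = "grouped_subject") -> pd.DataFrame:
    """Accuracy for each feature configuration x task, on shared splits.

    The same train/test split is reused for every configuration of a task
    so the rows are paired comparisons.
    """
    results: dict[str, dict[str, float]] = {}
    for task in tasks:
        roster = TASKS[task]
        task_data = dataset.filter_classes(roster) if roster else dataset
        train, test = split_dataset(task_data, mode=split_mode, seed=seed)
        col: dict[str, float] = {}
        for name, subset in ABLATION_CONFIGS.items():
            if name.endswith("ACO"):
                cfg = aco_config or ACOConfig(seed=seed)
                selection = run_aco(train, cfg)
                subset = selection.selected
            report = train_and_eval(train, test, replace(model, seed=seed),
                                    subset)
            col[name] = report.accuracy
        results[task] = col
    return pd.DataFrame(results)


def cv_grid(dataset: LabeledDataset,
            trees_list: Sequence[int] = (150, 200, 250, 300),
            folds_list: Sequence[int] = (5, 10), seed: int = 1,
            subset: Sequence[int] = tuple(range(1, 16))) -> pd.DataFrame:
    """Random Forest CV accuracy for every (trees, folds) cell."""
    if len(trees_list) == 0 or len(folds_list) == 0:
        raise ValueError("grids must be nonempty")
    X = dataset.columns_for(sorted(set(int(i) for i in subset)))
    y = np.asarray(dataset.labels)
    groups = np.asarray(dataset.groups)
    grid = pd.DataFrame(index=list(trees_list), columns=list(folds_list),
                        dtype=float)
    for folds in folds_list:
        cv = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                  random_state=seed)
        splits = list(cv.split(X, y, groups))
        for trees in trees_list:
            accs = []
            for train_idx, test_idx in splits:
                clf = RandomForestClassifier(n_estimators=trees,
                                             random_state=seed, n_jobs=1)
                clf.fit(X[train_idx], y[train_idx])
                accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
            grid.loc[trees, folds] = float(np.mean(accs))
    grid.index.name = "trees"
    grid.columns.name = "folds"
    return grid
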
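"""Ant Colony Optimization wrapper feature selection.

Candidate subsets of 4-8 of the 15 graph features are sampled in
proportion to per-feature pheromone levels, scored by cross-validated
Random Forest accuracy, and the pheromones of the iteration-best subset
are reinforced while all levels evaporate geometrically.  The canonical
minimal scheme is used: uniform initialization tau_f = 1, selection
probability proportional to tau alone (no heuristic-desirability term by
default), evaporation ``tau <- (1 - rho) tau`` followed by a deposit
``tau_f += Q * fitness_best`` on the features of the iteration-best
subset.  Defaults: 30 ants, 50 iterations, subset sizes 4-8, rho = 0.1,
Q = 1.

Fitness runs on training data only; the evaluator uses stratified
group-aware cross-validation so that no subject straddles a fold
boundary.  Fitness values are memoized per subset within a run, since
ants increasingly resample the same subsets as pheromones converge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold

from .dataset import LabeledDataset

__all__ = [
    "ACOConfig",
    "PheromoneState",
    "SelectionResult",
    "evaluate_subset",
    "run_aco",
    "selection_frequency",
    "anova_f_heuristic",
]


@dataclass(frozen=True)
class ACOConfig:
    n_ants: int = 30
    n_iterations: int = 50
    subset_min: int = 4
    subset_max: int = 8
    evaporation: float = 0.1
    deposit: float = 1.0
    fitness_folds: int = 5
    fitness_trees: int = 250
    use_heuristic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.subset_min <= self.subset_max:
            raise ValueError("need 1 <= subset_min <= subset_max")
        if self.n_ants < 1 or self.n_iterations < 1:
            raise ValueError("n_ants and n_iterations must be >= 1")
        if not 0 < self.evaporation < 1:
            raise ValueError("evaporation must lie in (0, 1)")


@dataclass
class PheromoneState:
    """Per-feature pheromone levels and the best-so-far fitness trace."""

    tau: np.ndarray
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.tau <= 0):
            raise ValueError("pheromone levels must stay positive")


@dataclass
class SelectionResult:
    selected: list[int]          # 1-based feature indices, sorted
    fitness: float
    trace: list[float]           # best-so-far fitness per iteration
    pheromone_final: PheromoneState
    seed: int
    n_evaluations: int = 0


def evaluate_subset(dataset: LabeledDataset, subset: Sequence[int],
                    folds: int = 5, seed: int = 0,
                    n_trees: int = 250) -> float:
    """Mean CV accuracy of a seeded Random Forest on the subset's columns.

    Cross-validation is stratified by class and grouped by subject, so
    samples of one subject never appear on both sides of a fold.
    """
    subset = sorted(set(int(i) for i in subset))
    if not subset:
        raise ValueError("feature subset must be nonempty")
    y = np.asarray(dataset.labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; use at most "
            f"{counts.min()} folds"
        )
    X = dataset.columns_for(subset)
    groups = np.asarray(dataset.groups)
    cv = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in cv.split(X, y, groups):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                     n_jobs=1)
        clf.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def anova_f_heuristic(dataset: LabeledDataset,
                      n_features: int = 15) -> np.ndarray:
    """Optional per-feature desirability: one-way ANOVA F-scores."""
    from sklearn.feature_selection import f_classif

    X = dataset.columns_for(range(1, n_features + 1))
    f, _ = f_classif(X, np.asarray(dataset.labels))
    f = np.nan_to_num(f, nan=0.0)
    return f + 1e-12


def run_aco(dataset: LabeledDataset | None, config: ACOConfig,
            fitness_fn: Callable[[tuple[int, ...]], float] | None = None,
            n_features: int = 15) -> SelectionResult:
    """Run the colony and return the best-ever subset.

    ``fitness_fn`` overrides the cross-validated classifier fitness with
    an arbitrary map from a sorted 1-based index tuple to a score (used
    for planted-optimum testing and for fast experimentation);
    ``dataset`` may then be ``None``.
    """
    if fitness_fn is None:
        if dataset is None:
            raise ValueError("need a dataset when no fitness_fn is injected")
        if dataset.n_features < config.subset_max:
            raise ValueError(
                f"dataset has {dataset.n_features} features, fewer than "
                f"subset_max={config.subset_max}"
            )
        n_features = dataset.n_features

        def fitness_fn(subset: tuple[int, ...]) -> float:
            return evaluate_subset(dataset, subset, folds=config.fitness_folds,
                                   seed=config.seed,
                                   n_trees=config.fitness_trees)

    rng = np.random.default_rng(config.seed)
    tau = np.ones(n_features)
    eta = np.ones(n_features)
    if config.use_heuristic and dataset is not None:
        eta = anova_f_heuristic(dataset, n_features)
    cache: dict[tuple[int, ...], float] = {}
    best_subset: tuple[int, ...] | None = None
    best_fitness = -np.inf
    trace: list[float] = []

    for _ in range(config.n_iterations):
        iter_best: tuple[int, ...] | None = None
        iter_fitness = -np.inf
        for _ant in range(config.n_ants):
            size = int(rng.integers(config.subset_min, config.subset_max + 1))
            p = tau * eta
            p = p / p.sum()
            picked = rng.choice(n_features, size=size, replace=False, p=p)
            subset = tuple(sorted(int(f) + 1 for f in picked))
            if subset not in cache:
                cache[subset] = float(fitness_fn(subset))
            fit = cache[subset]
            if fit > iter_fitness:
                iter_fitness, iter_best = fit, subset
        tau *= 1.0 - config.evaporation
        for f in iter_best:
            tau[f - 1] += config.deposit * iter_fitness
        if iter_fitness > best_fitness:
            best_fitness, best_subset = iter_fitness, iter_best
        trace.append(best_fitness)

    return SelectionResult(
        selected=list(best_subset),
        fitness=best_fitness,
        trace=trace,
        pheromone_final=PheromoneState(tau=tau, history=trace),
        seed=config.seed,
        n_evaluations=len(cache),
    )


def selection_frequency(dataset: LabeledDataset | None, config: ACOConfig,
                        n_runs: int,
                        fitness_fn: Callable[[tuple[int, ...]], float] | None = None,
                        n_features: int = 15) -> pd.Series:
    """Percent of independent runs whose final subset contains each feature.

    Run seeds are derived deterministically from ``config.seed``.  When no
    ``fitness_fn`` is injected, the cross-validated fitness is evaluated
    with the *master* seed for every run, so all colonies search one
    deterministic fitness landscape and the frequencies measure search
    variability rather than CV-resampling noise; fitness values are
    memoized across runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if dataset is not None and fitness_fn is None:
        n_features = dataset.n_features
        cache: dict[tuple[int, ...], float] = {}
        master = config.seed

        def fitness_fn(subset: tuple[int, ...]) -> float:
            if subset not in cache:
                cache[subset] = evaluate_subset(
                    dataset, subset, folds=config.fitness_folds,
                    seed=master, n_trees=config.fitness_trees)
            return cache[subset]

    counts = np.zeros(n_features)
    children = np.random.SeedSequence(config.seed).spawn(n_runs)
    for child in children:
        run_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = ACOConfig(
            n_ants=config.n_ants, n_iterations=config.n_iterations,
            subset_min=config.subset_min, subset_max=config.subset_max,
            evaporation=config.evaporation, deposit=config.deposit,
            fitness_folds=config.fitness_folds,
            fitness_trees=config.fitness_trees,
            use_heuristic=config.use_heuristic, seed=run_seed,
        )
        result = run_aco(dataset, cfg, fitness_fn=fitness_fn,
                         n_features=n_features)
        for f in result.selected:
            counts[f - 1] += 1
    freq = 100.0 * counts / n_runs
    return pd.Series(freq, index=pd.RangeIndex(1, n_features + 1,
                                               name="feature"))
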
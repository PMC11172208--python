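"""Wrapper feature selection with a sparsity-penalized k-NN fitness.

A candidate solution is a real vector in [0,1]^dim; coordinates above 0.5
switch the corresponding feature column on. The fitness of a mask F is

    f = w · η(F) + (1 − w) · |F| / dim,

minimized, where η is the validation error rate of a k-nearest-neighbour
classifier trained on the selected columns and w (default 0.99) trades
classification performance against subset size. The empty mask is
infeasible (a classifier cannot be scored on zero features) and receives
the worst sentinel.

Data handling: the problem splits its samples once into a stratified
train/test partition (default 70/30). Selection only ever sees the training
partition — the fitness internally re-splits it 70/30 (stratified, seeded)
into fit/validation folds — and the test partition is reserved for the
final report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .core import OptimizerConfig, SearchBounds, WORST_FITNESS
from .cuckoo import OptimizationTrace, run_cs
from .fractional_cuckoo import run_cfo_cs
from .metrics import MetricReport, compute_metrics, confusion_counts

METHODS = {"cs": run_cs, "cfo_cs": run_cfo_cs}


@dataclass(frozen=True)
class BinaryMask:
    """0/1 feature-inclusion vector."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=np.int8)
        if mask.ndim != 1 or not np.isin(mask, (0, 1)).all():
            raise ValueError("mask must be a 1-D 0/1 vector")
        object.__setattr__(self, "mask", mask)

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    @property
    def dim(self) -> int:
        return int(self.mask.shape[0])

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def key(self) -> bytes:
        return self.mask.tobytes()


def binarize(position: np.ndarray) -> BinaryMask:
    """Threshold a real position at 0.5 (strict: exactly 0.5 maps to 0)."""
    position = np.asarray(position, dtype=float)
    return BinaryMask((position > 0.5).astype(np.int8))


def fitness(mask: BinaryMask, eta: float, dim: int, fitness_weight: float) -> float:
    """Sparsity-penalized error: w·η + (1−w)·|F|/dim; empty mask → sentinel."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if mask.count > dim:
        raise ValueError("mask selects more features than exist")
    if not 0.0 <= fitness_weight <= 1.0:
        raise ValueError("fitness_weight must lie in [0, 1]")
    if mask.count == 0:
        return WORST_FITNESS
    return fitness_weight * eta + (1.0 - fitness_weight) * mask.count / dim


def knn_error(
    features: np.ndarray,
    labels: np.ndarray,
    mask: BinaryMask,
    k: int = 7,
    split_fraction: float = 0.70,
    seed: int | None = 0,
) -> float:
    """Hold-out validation error of k-NN (Euclidean) on the masked columns.

    The data is split stratified at ``split_fraction`` (train side); the
    classifier is fit on the training side and scored on the held-out side.
    Returns the error rate 1 − accuracy in [0, 1].
    """
    if mask.count == 0:
        raise ValueError("cannot evaluate an empty feature mask")
    if k < 1:
        raise ValueError("k must be >= 1")
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    cols = mask.selected_indices
    x_tr, x_va, y_tr, y_va = train_test_split(
        features[:, cols],
        labels,
        train_size=split_fraction,
        stratify=labels,
        random_state=seed,
    )
    if k > len(y_tr):
        raise ValueError(f"k={k} exceeds training-set size {len(y_tr)}")
    clf = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    clf.fit(x_tr, y_tr)
    return float(1.0 - clf.score(x_va, y_va))


@dataclass
class FeatureSelectionProblem:
    """A labeled feature matrix plus the evaluation protocol around it.

    ``evaluator`` may override the default k-NN hold-out error: it receives
    ``(features, labels, mask, seed)`` restricted to the training partition
    and must return an error rate in [0, 1].
    """

    features: np.ndarray
    labels: np.ndarray
    split_fraction: float = 0.70
    fitness_weight: float = 0.99
    n_neighbors: int = 7
    seed: int = 0
    evaluator: Callable | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features must be (n_samples, dim) matching labels")
        if not 0.0 <= self.fitness_weight <= 1.0:
            raise ValueError("fitness_weight must lie in [0, 1]")
        if np.unique(self.labels).size < 2:
            raise ValueError("labels must contain both classes")
        idx = np.arange(self.features.shape[0])
        self._train_idx, self._test_idx = train_test_split(
            idx,
            train_size=self.split_fraction,
            stratify=self.labels,
            random_state=self.seed,
        )

    @property
    def dim(self) -> int:
        return int(self.features.shape[1])

    @property
    def train_data(self) -> tuple[np.ndarray, np.ndarray]:
        return self.features[self._train_idx], self.labels[self._train_idx]

    @property
    def test_data(self) -> tuple[np.ndarray, np.ndarray]:
        return self.features[self._test_idx], self.labels[self._test_idx]

    def validation_error(self, mask: BinaryMask) -> float:
        """η for the fitness: hold-out error inside the training partition."""
        x_tr, y_tr = self.train_data
        if self.evaluator is not None:
            return float(self.evaluator(x_tr, y_tr, mask, self.seed))
        return knn_error(
            x_tr, y_tr, mask, k=self.n_neighbors,
            split_fraction=self.split_fraction, seed=self.seed,
        )

    def make_objective(self) -> Callable[[np.ndarray], float]:
        """Real-vector objective with a per-mask memo of η.

        Many positions binarize to the same mask (and the optimizer's
        finite-difference stencils probe near-identical positions), so η is
        cached by mask; the cache changes nothing but wall time.
        """
        cache: dict[bytes, float] = {}

        def objective(x: np.ndarray) -> float:
            m = binarize(x)
            if m.count == 0:
                return WORST_FITNESS
            key = m.key()
            eta = cache.get(key)
            if eta is None:
                eta = self.validation_error(m)
                cache[key] = eta
            return fitness(m, eta, self.dim, self.fitness_weight)

        return objective

    def test_report(self, mask: BinaryMask) -> MetricReport:
        """Final metrics: k-NN fit on the full training partition, scored on
        the untouched test partition."""
        x_tr, y_tr = self.train_data
        x_te, y_te = self.test_data
        cols = mask.selected_indices
        clf = KNeighborsClassifier(n_neighbors=self.n_neighbors, metric="euclidean")
        clf.fit(x_tr[:, cols], y_tr)
        y_pred = clf.predict(x_te[:, cols])
        return compute_metrics(confusion_counts(y_te, y_pred))


@dataclass
class SelectionResult:
    mask: BinaryMask
    fitness: float
    trace: OptimizationTrace
    selected_indices: np.ndarray


def select_features(
    problem: FeatureSelectionProblem,
    config: OptimizerConfig,
    method: str = "cfo_cs",
) -> SelectionResult:
    """Run the chosen optimizer over [0,1]^dim and return the best mask."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    bounds = SearchBounds.unit(problem.dim)
    objective = problem.make_objective()
    trace = METHODS[method](objective, bounds, config)
    if not np.isfinite(trace.best_fitness):
        raise RuntimeError("no feasible mask found: every evaluation was infeasible")
    mask = binarize(trace.best_position)
    eta = problem.validation_error(mask)
    return SelectionResult(
        mask=mask,
        fitness=fitness(mask, eta, problem.dim, problem.fitness_weight),
        trace=trace,
        selected_indices=mask.selected_indices,
    )
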
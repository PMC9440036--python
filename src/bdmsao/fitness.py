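"""Wrapper fitness: binarization, KNN accuracy and the composite objective.

A continuous mongoose position in ``[0,1]^D`` is thresholded into a binary
feature mask (strictly greater than 0.5 selects a feature).  A mask is scored
by the pooled k-nearest-neighbour cross-validation accuracy ``A_c`` on the
selected features, combined with a subset-size penalty into the minimised
objective

    fitness = mu * (1 - A_c) + (1 - mu) * d_s / D_t

with ``mu = 0.99`` by default, ``d_s`` the number of selected features and
``D_t`` the total feature count.  Accuracy therefore dominates, and the size
term breaks ties between equally accurate subsets in favour of smaller ones.

The KNN here is deliberately fully specified: Euclidean distance on
min-max-scaled features (scaling fit on each fold's training part), majority
vote over the k nearest training points, neighbour-distance ties broken by the
smallest training index and vote ties by the smallest class label.  Pinning
the tie-breaks makes every fitness value reproducible bit-for-bit, which the
search and the exhaustive oracle both rely on; agreement with scikit-learn's
``KNeighborsClassifier`` is checked in the test suite.

:class:`MaskEvaluator` pre-computes the per-fold scaled matrices once and
memoizes fitness by mask bits, because KNN cross-validation is the dominant
cost of a search run and identical masks recur constantly.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from .datasets import Dataset, FoldPlan, make_folds
from .exceptions import ConfigError, NumericError

__all__ = [
    "FeatureMask",
    "FitnessConfig",
    "FitnessValue",
    "binarize",
    "knn_accuracy",
    "evaluate",
    "MaskEvaluator",
]


@dataclass(frozen=True)
class FeatureMask:
    """A candidate feature subset as a 0/1 vector of length ``D_t``."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        b = np.ascontiguousarray(np.asarray(self.bits), dtype=np.uint8)
        if b.ndim != 1 or not np.isin(b, (0, 1)).all():
            raise NumericError("mask bits must be a 1-D 0/1 vector")
        object.__setattr__(self, "bits", b)

    @property
    def d_s(self) -> int:
        """Number of selected features."""
        return int(self.bits.sum())

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def key(self) -> bytes:
        return self.bits.tobytes()

    def to01(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def feature_names(self, dataset: Dataset) -> list[str]:
        return [dataset.feature_names[j] for j in self.selected]

    def __len__(self) -> int:
        return self.bits.size

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureMask) and np.array_equal(
            self.bits, other.bits
        )

    def __hash__(self) -> int:
        return hash(self.key())


@dataclass(frozen=True)
class FitnessConfig:
    """Evaluation settings for the wrapper objective.

    ``mu`` weighs classification error against subset size; ``eval_mode`` is
    pooled cross-validation (``"cv"``) or a single stratified holdout split
    (``"holdout"``, fraction ``test_fraction`` held out).
    """

    mu: float = 0.99
    knn_k: int = 5
    cv_folds: int = 10
    eval_mode: str = "cv"
    seed: int = 0
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ConfigError(f"mu must be in [0,1], got {self.mu}")
        if self.knn_k < 1:
            raise ConfigError("knn_k must be >= 1")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.eval_mode not in ("cv", "holdout"):
            raise ConfigError(f"unknown eval_mode {self.eval_mode!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be in (0,1)")


@functools.total_ordering
@dataclass(frozen=True)
class FitnessValue:
    """The composite objective with its components retained.

    Ordering is the search's preference order: lower fitness, then fewer
    selected features, then lexicographically lower selected indices.  The
    latter two only matter for exact fitness ties and make "number of
    features selected" deterministic in reports.
    """

    fitness: float
    accuracy: float
    size_penalty: float
    d_s: int
    selected_key: tuple = ()

    def sort_key(self):
        return (self.fitness, self.d_s, self.selected_key)

    def __lt__(self, other: "FitnessValue") -> bool:
        return self.sort_key() < other.sort_key()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FitnessValue)
            and self.sort_key() == other.sort_key()
        )


def binarize(position, rng: np.random.Generator | None = None) -> FeatureMask:
    """Threshold a continuous position into a feature mask.

    Entries are clamped to ``[0,1]`` first; a feature is selected iff its
    (clamped) coordinate is strictly greater than 0.5.  An all-zero result is
    repaired by selecting the coordinate with the largest continuous value
    (ties to the lowest index); if all coordinates are exactly equal a random
    bit is set (first bit without an ``rng``), since a classifier needs at
    least one feature.
    """
    pos = np.asarray(position, dtype=float)
    if pos.ndim != 1:
        raise NumericError("position must be a 1-D vector")
    if not np.isfinite(pos).all():
        raise NumericError("position contains non-finite entries")
    clamped = np.clip(pos, 0.0, 1.0)
    bits = (clamped > 0.5).astype(np.uint8)
    if not bits.any():
        if np.ptp(clamped) == 0.0:
            idx = int(rng.integers(bits.size)) if rng is not None else 0
        else:
            idx = int(np.argmax(clamped))
        bits[idx] = 1
    return FeatureMask(bits)


def _as_mask(position_or_mask, rng=None) -> FeatureMask:
    if isinstance(position_or_mask, FeatureMask):
        return position_or_mask
    return binarize(position_or_mask, rng=rng)


class MaskEvaluator:
    """Memoized KNN-wrapper fitness for one dataset + configuration.

    Pre-computes min-max-scaled train/eval matrices for every fold so that a
    mask evaluation reduces to a masked pairwise-distance computation.
    ``n_calls`` counts every fitness request, ``n_knn_evals`` the cache
    misses that actually ran the classifier.
    """

    def __init__(
        self,
        dataset: Dataset,
        config: FitnessConfig | None = None,
        fold_plan: FoldPlan | None = None,
    ) -> None:
        config = config or FitnessConfig()
        if dataset.n_classes < 2:
            raise ConfigError("wrapper fitness requires at least 2 classes")
        self.dataset = dataset
        self.config = config
        self._splits: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        if config.eval_mode == "cv":
            plan = fold_plan or make_folds(dataset, config.cv_folds, config.seed)
            pairs = [plan.fold_indices(f) for f in range(plan.k)]
            self.fold_plan = plan
        else:
            train_idx, test_idx = self._holdout_split(dataset, config)
            pairs = [(train_idx, test_idx)]
            self.fold_plan = None
        X, y = dataset.features, dataset.labels
        for train_idx, test_idx in pairs:
            if config.knn_k >= train_idx.size:
                raise ConfigError(
                    f"knn_k={config.knn_k} must be smaller than the "
                    f"training-set size {train_idx.size}"
                )
            lo = X[train_idx].min(axis=0)
            rng_ = X[train_idx].max(axis=0) - lo
            rng_[rng_ == 0.0] = 1.0  # constant feature: scaled to 0 everywhere
            train_s = (X[train_idx] - lo) / rng_
            test_s = (X[test_idx] - lo) / rng_
            self._splits.append((train_s, y[train_idx], test_s, y[test_idx]))
        self._n_eval_total = sum(s[3].size for s in self._splits)
        self._cache: dict[bytes, FitnessValue] = {}
        self.n_calls = 0
        self.n_knn_evals = 0

    @staticmethod
    def _holdout_split(dataset: Dataset, config: FitnessConfig):
        rng = np.random.default_rng(config.seed)
        test_mask = np.zeros(dataset.n_samples, dtype=bool)
        for c in np.unique(dataset.labels):
            idx = np.flatnonzero(dataset.labels == c)
            idx = rng.permutation(idx)
            n_test = max(1, round(config.test_fraction * idx.size))
            test_mask[idx[:n_test]] = True
        return np.flatnonzero(~test_mask), np.flatnonzero(test_mask)

    def _knn_correct(self, mask: FeatureMask) -> int:
        """Correct predictions pooled over all splits for this mask."""
        cols = mask.selected
        k = self.config.knn_k
        n_classes = self.dataset.n_classes
        correct = 0
        for train_s, train_y, test_s, test_y in self._splits:
            a = test_s[:, cols]
            b = train_s[:, cols]
            # squared Euclidean distances, (n_test, n_train)
            d2 = (
                (a * a).sum(axis=1)[:, None]
                - 2.0 * (a @ b.T)
                + (b * b).sum(axis=1)[None, :]
            )
            # k nearest with ties by smallest training index: stable argsort
            order = np.argsort(d2, axis=1, kind="stable")[:, :k]
            votes = train_y[order]
            counts = np.zeros((votes.shape[0], n_classes), dtype=int)
            for j in range(k):
                np.add.at(counts, (np.arange(votes.shape[0]), votes[:, j]), 1)
            pred = counts.argmax(axis=1)  # vote ties -> smallest label
            correct += int((pred == test_y).sum())
        return correct

    def accuracy(self, mask: FeatureMask) -> float:
        """Pooled evaluation accuracy ``A_c`` of one mask."""
        if mask.d_s < 1:
            raise ConfigError("mask selects no features")
        return self._knn_correct(mask) / self._n_eval_total

    def __call__(self, position_or_mask) -> FitnessValue:
        mask = _as_mask(position_or_mask)
        self.n_calls += 1
        key = mask.key()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        self.n_knn_evals += 1
        acc = self.accuracy(mask)
        mu = self.config.mu
        size_penalty = (1.0 - mu) * mask.d_s / len(mask)
        fv = FitnessValue(
            fitness=mu * (1.0 - acc) + size_penalty,
            accuracy=acc,
            size_penalty=size_penalty,
            d_s=mask.d_s,
            selected_key=tuple(int(j) for j in mask.selected),
        )
        self._cache[key] = fv
        return fv


def knn_accuracy(
    mask: FeatureMask, dataset: Dataset, config: FitnessConfig | None = None
) -> float:
    """One-shot pooled KNN accuracy of a mask (no caching across calls)."""
    return MaskEvaluator(dataset, config).accuracy(mask)


def evaluate(
    position_or_mask, dataset: Dataset, config: FitnessConfig | None = None
) -> FitnessValue:
    """One-shot composite fitness of a position or mask."""
    return MaskEvaluator(dataset, config)(position_or_mask)
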
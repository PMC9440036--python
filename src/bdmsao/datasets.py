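"""Tabular classification datasets and cross-validation fold plans.

A :class:`Dataset` is an ``n_samples x n_features`` real matrix plus integer
class labels; it is the object every other module consumes.  Readers are
provided for CSV (RFC-4180-style, header row required) and ARFF.  Labels are
encoded to contiguous integers ``0..C-1`` in order of first appearance, which
keeps small hand-written fixtures predictable regardless of label spelling.

Fold construction wraps scikit-learn's splitters and freezes the assignment
into a :class:`FoldPlan` so the same partition can be reused, serialized and
asserted on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import ConfigError, InputError

__all__ = [
    "Dataset",
    "FoldPlan",
    "read_csv_dataset",
    "read_arff_dataset",
    "make_folds",
]


@dataclass
class Dataset:
    """A samples-by-features classification problem.

    Parameters
    ----------
    features
        Real-valued matrix of shape ``(n_samples, n_features)``.
    labels
        Integer class per sample, encoded ``0..C-1``.
    feature_names
        One name per column.
    name
        Identifier used in reports.
    allow_single_class
        Permit a degenerate single-class dataset (the wrapper fitness will
        still refuse to evaluate it; this flag only relaxes construction).
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    name: str = "dataset"
    allow_single_class: bool = False

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise InputError("features must be a 2-D matrix")
        n, d = self.features.shape
        if n < 2:
            raise InputError(f"need at least 2 samples, got {n}")
        if d < 1:
            raise InputError("need at least 1 feature")
        if self.labels.shape != (n,):
            raise InputError(
                f"labels length {self.labels.shape} does not match n_samples {n}"
            )
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(d)]
        if len(self.feature_names) != d:
            raise InputError("feature_names length does not match feature count")
        if not self.allow_single_class and np.unique(self.labels).size < 2:
            raise InputError(
                "dataset has a single class; pass allow_single_class=True "
                "if this is intentional"
            )

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        """Total attribute count D_t, the denominator of the size penalty."""
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.labels).size)

    def to_csv(self, path, label_column: str = "class", delimiter: str = ",") -> None:
        """Write the dataset in the same dialect :func:`read_csv_dataset` reads."""
        frame = pd.DataFrame(self.features, columns=self.feature_names)
        frame[label_column] = self.labels
        # %.17g round-trips IEEE doubles exactly
        frame.to_csv(path, index=False, sep=delimiter, float_format="%.17g")


@dataclass(frozen=True)
class FoldPlan:
    """A frozen k-fold partition: ``assignments[i]`` is sample i's fold."""

    k: int
    assignments: np.ndarray
    seed: int
    stratified: bool

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=int)
        object.__setattr__(self, "assignments", a)
        if a.min(initial=0) < 0 or (a.size and a.max() >= self.k):
            raise ConfigError("fold assignments out of range")

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (train_idx, test_idx) for one fold."""
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test


def _encode_labels(raw: pd.Series) -> tuple[np.ndarray, list]:
    """Map labels to 0..C-1 in first-appearance order."""
    seen: dict = {}
    out = np.empty(len(raw), dtype=int)
    for i, v in enumerate(raw):
        if v not in seen:
            seen[v] = len(seen)
        out[i] = seen[v]
    return out, list(seen)


def read_csv_dataset(
    path,
    label_column: str | int = "class",
    delimiter: str = ",",
    name: str | None = None,
) -> Dataset:
    """Read a header-row CSV into a :class:`Dataset`.

    ``label_column`` may be a column name or a 0-based column index.  All
    non-label cells must be numeric; the first offending cell is reported by
    row and column.
    """
    frame = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if isinstance(label_column, int):
        if not 0 <= label_column < frame.shape[1]:
            raise ConfigError(
                f"label column index {label_column} out of range for "
                f"{frame.shape[1]} columns"
            )
        label_name = frame.columns[label_column]
    else:
        label_name = label_column
        if label_name not in frame.columns:
            raise ConfigError(f"label column {label_name!r} not found in {path}")

    labels, _ = _encode_labels(frame[label_name])
    feature_frame = frame.drop(columns=[label_name])
    numeric = feature_frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise InputError(
            f"non-numeric or missing value at row {row}, column {col!r} "
            f"(value {feature_frame.loc[row, col]!r})"
        )
    return Dataset(
        features=numeric.to_numpy(dtype=float),
        labels=labels,
        feature_names=[str(c) for c in feature_frame.columns],
        name=name or str(path),
    )


def read_arff_dataset(path, class_attribute: str | None = None) -> Dataset:
    """Read an ARFF file; the class attribute defaults to the last nominal one.

    Nominal attributes other than the class are rejected rather than silently
    one-hot expanded, which would change the total feature count.
    """
    data, meta = scipy_arff.loadarff(path)
    nominal = [n for n in meta.names() if meta[n][0] == "nominal"]
    if class_attribute is None:
        if not nominal:
            raise InputError("ARFF file has no nominal attribute to use as class")
        class_attribute = nominal[-1]
    if class_attribute not in meta.names():
        raise ConfigError(f"class attribute {class_attribute!r} not in ARFF header")
    extra_nominal = [n for n in nominal if n != class_attribute]
    if extra_nominal:
        raise InputError(
            f"non-class nominal attributes are not supported: {extra_nominal}"
        )
    raw_labels = data[class_attribute]
    if raw_labels.dtype.kind == "S":
        raw_labels = np.char.decode(raw_labels)
    labels, _ = _encode_labels(pd.Series(raw_labels))
    feat_names = [n for n in meta.names() if n != class_attribute]
    features = np.column_stack([data[n].astype(float) for n in feat_names])
    if np.isnan(features).any():
        i, j = np.argwhere(np.isnan(features))[0]
        raise InputError(
            f"missing value at row {i}, attribute {feat_names[j]!r}"
        )
    return Dataset(features, labels, feat_names, name=str(path))


def make_folds(
    dataset: Dataset, k: int, seed: int, stratified: bool = True
) -> FoldPlan:
    """Build a deterministic k-fold plan.

    Stratified by default; if any class has fewer than ``k`` members the plan
    falls back to unstratified shuffled folds with a warning.
    """
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    if k > dataset.n_samples:
        raise ConfigError(
            f"k={k} exceeds the sample count {dataset.n_samples}"
        )
    use_strat = stratified
    if stratified:
        counts = np.bincount(dataset.labels)
        if counts[counts > 0].min() < k:
            warnings.warn(
                "a class has fewer samples than folds; "
                "falling back to unstratified folds",
                stacklevel=2,
            )
            use_strat = False
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if use_strat
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    assignments = np.empty(dataset.n_samples, dtype=int)
    for fold, (_, test_idx) in enumerate(
        splitter.split(dataset.features, dataset.labels)
    ):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed, stratified=use_strat)
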
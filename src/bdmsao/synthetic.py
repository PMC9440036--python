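"""Synthetic classification problems with planted feature subsets.

The generators produce datasets whose informative-feature set is known, so
feature-selection runs can be scored against ground truth without any
external download.  Two shapes are emulated:

* :func:`make_planted` — UCI-style tabular problems (tens of features,
  around a hundred samples), and
* :func:`make_expression_like` — microarray-style problems (thousands of
  positive-valued features, a few dozen samples).

Informative features carry a class-dependent mean shift; noise features are
class-independent standard Gaussians.  ``class_sep`` is the Euclidean
(Mahalanobis, since features are homoscedastic unit-variance) distance
between *adjacent class centroids over the whole informative block*: the
per-feature shift is ``class_sep / sqrt(n_informative)``.  Pinning the
centroid distance rather than a per-feature shift means that no small
sub-subset of the informative features is individually sufficient — dropping
informative features genuinely costs accuracy — which keeps the optimal
subset of the wrapper objective analytically predictable (all informative
features, no noise features, for reasonable separations).

:func:`exhaustive_oracle` enumerates every nonempty mask on small problems
with the identical evaluator and tie-breaking as the search, providing the
ground-truth optimum the metaheuristic is measured against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import Dataset
from .exceptions import ConfigError
from .fitness import FeatureMask, FitnessConfig, FitnessValue, MaskEvaluator

__all__ = [
    "PlantedSpec",
    "make_planted",
    "make_expression_like",
    "exhaustive_oracle",
]


@dataclass(frozen=True)
class PlantedSpec:
    """Recipe for a planted-subset classification dataset.

    ``class_sep`` is the centroid separation of adjacent classes across the
    informative block, in within-class standard deviations.  ``label_noise``
    flips that fraction of labels to a uniformly chosen other class.
    """

    n_samples: int = 100
    n_informative: int = 5
    n_noise: int = 45
    n_classes: int = 2
    class_sep: float = 4.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ConfigError("need at least one informative feature")
        if self.n_noise < 0:
            raise ConfigError("n_noise must be >= 0")
        if self.n_classes < 2:
            raise ConfigError("need at least two classes")
        if not 0.0 <= self.label_noise < 0.5:
            raise ConfigError("label_noise must lie in [0, 0.5)")
        if self.n_samples < 2 * self.n_classes:
            raise ConfigError("need at least two samples per class")
        if self.class_sep < 0:
            raise ConfigError("class_sep must be >= 0")


def _planted_matrix(spec: PlantedSpec, rng: np.random.Generator):
    """Raw (features, labels, informative index set) for a planted spec."""
    n, k = spec.n_samples, spec.n_informative
    d = k + spec.n_noise
    # near-balanced classes, shuffled
    labels = np.arange(n) % spec.n_classes
    rng.shuffle(labels)
    X = rng.standard_normal((n, d))
    # classes laid out along a line in the informative block: adjacent class
    # centroids are class_sep apart, shared equally by the k features
    shift = spec.class_sep / np.sqrt(k)
    X[:, :k] += shift * labels[:, None]
    if spec.label_noise > 0:
        n_flip = round(spec.label_noise * n)
        flip = rng.choice(n, size=n_flip, replace=False)
        offsets = rng.integers(1, spec.n_classes, size=n_flip)
        labels[flip] = (labels[flip] + offsets) % spec.n_classes
    # informative columns scattered among the noise columns
    perm = rng.permutation(d)
    X = X[:, perm]
    truth = np.sort(np.argsort(perm)[:k])
    return X, labels, truth


def make_planted(spec: PlantedSpec) -> tuple[Dataset, np.ndarray]:
    """Generate a planted dataset; returns it with the informative indices."""
    rng = np.random.default_rng(spec.seed)
    X, labels, truth = _planted_matrix(spec, rng)
    names = [
        f"inf{j}" if j in set(truth.tolist()) else f"noise{j}"
        for j in range(X.shape[1])
    ]
    ds = Dataset(
        X,
        labels,
        [f"{n}_{j}" for j, n in enumerate(names)],
        name=f"planted_d{X.shape[1]}_s{spec.seed}",
    )
    return ds, truth


def make_expression_like(
    n_samples: int = 62,
    n_features: int = 2000,
    n_informative: int = 10,
    class_sep: float = 6.0,
    seed: int = 0,
    n_classes: int = 2,
) -> tuple[Dataset, np.ndarray]:
    """Expression-style dataset: few samples, thousands of positive features.

    The planted structure is generated in log space and exponentiated, giving
    log-normal-like positive intensities with the class signal preserved
    monotonically.  Default shape (62 x 2000) mirrors classic colon-cancer
    microarray dimensions.
    """
    if n_features < n_informative:
        raise ConfigError("n_features must be >= n_informative")
    spec = PlantedSpec(
        n_samples=n_samples,
        n_informative=n_informative,
        n_noise=n_features - n_informative,
        n_classes=n_classes,
        class_sep=class_sep,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    L, labels, truth = _planted_matrix(spec, rng)
    X = np.exp(0.35 * L + 2.0)  # positive, log-normal-like intensities
    ds = Dataset(
        X,
        labels,
        [f"g{j}" for j in range(n_features)],
        name=f"expression_{n_samples}x{n_features}_s{seed}",
    )
    return ds, truth


def exhaustive_oracle(
    dataset: Dataset,
    fit_config: FitnessConfig | None = None,
    max_dim: int = 20,
) -> tuple[FeatureMask, FitnessValue]:
    """Globally optimal mask by brute force over all ``2^D - 1`` subsets.

    Uses the identical evaluator and tie-breaking as the search, so a search
    result can be compared to the optimum by exact equality.  Refuses more
    than ``max_dim`` features (the enumeration is exponential).
    """
    d = dataset.n_features
    if d > max_dim:
        raise ConfigError(
            f"exhaustive enumeration refused for {d} > max_dim={max_dim} features"
        )
    evaluator = MaskEvaluator(dataset, fit_config)
    best_mask: FeatureMask | None = None
    best: FitnessValue | None = None
    for code in range(1, 2**d):
        bits = (code >> np.arange(d)) & 1
        mask = FeatureMask(bits.astype(np.uint8))
        fv = evaluator(mask)
        if best is None or fv < best:
            best_mask, best = mask, fv
    assert best_mask is not None and best is not None
    return best_mask, best
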
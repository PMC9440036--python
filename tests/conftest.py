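import numpy as np
import pytest

from bdmsao import (
    DMOParams,
    FitnessConfig,
    MaskEvaluator,
    PlantedSpec,
    make_planted,
)


@pytest.fixture(scope="session")
def small_planted():
    """10-feature planted dataset (3 informative), enumerable exhaustively."""
    ds, truth = make_planted(
        PlantedSpec(n_samples=60, n_informative=3, n_noise=7, class_sep=4.0, seed=11)
    )
    return ds, truth


@pytest.fixture(scope="session")
def small_evaluator(small_planted):
    ds, _ = small_planted
    return MaskEvaluator(ds, FitnessConfig(cv_folds=5, seed=0))


@pytest.fixture(scope="session")
def medium_planted():
    """50-feature planted dataset (5 informative) for search behavior tests."""
    return make_planted(
        PlantedSpec(n_samples=100, n_informative=5, n_noise=45, class_sep=4.0, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quick_dmo_params():
    """Small search budget for fast driver tests."""
    def _make(d, seed=0, **kw):
        defaults = dict(d=d, n=6, max_iter=10, n_babysitters=2, seed=seed)
        defaults.update(kw)
        return DMOParams(**defaults)

    return _make
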
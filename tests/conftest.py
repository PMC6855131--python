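import numpy as np
import pytest

from neurofuse.cohort import CohortSpec, generate_cohort
from neurofuse.crossval import ClassifierSpec, make_folds


def small_spec(**overrides) -> CohortSpec:
    """Compact two-modality cohort spec for fast tests."""
    base = dict(
        n_voxels=200,
        n_controls=40,
        n_patients=40,
        modality_names=("A", "B"),
        signal_count_per_modality=30,
        effect_size_per_modality=1.5,
        noise_sd=1.0,
        seed=7,
    )
    base.update(overrides)
    return CohortSpec(**base)


@pytest.fixture
def small_cohort():
    return generate_cohort(small_spec())


@pytest.fixture
def small_plan(small_cohort):
    return make_folds(small_cohort.labels, n_folds=5, seed=11)


@pytest.fixture
def fast_ridge():
    return ClassifierSpec("ridge", seed=0, n_penalties=4, internal_cv=3)


@pytest.fixture
def fast_lasso():
    return ClassifierSpec("lasso", seed=0, n_penalties=4, internal_cv=3)


@pytest.fixture
def fast_forest():
    return ClassifierSpec("random_forest", seed=0, n_trees=60)


@pytest.fixture
def fast_boost():
    return ClassifierSpec(
        "gradient_boosting", seed=0, internal_cv=3, gb_depths=(1, 2), gb_shrinkages=(0.1,),
        gb_max_trees=30,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
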
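import numpy as np
import pytest

import deltarad as dr


def feature_delta(
    effect_size: float,
    seed: int,
    n_per_class: int = 30,
    n_features: int = 20,
    n_informative: int = 3,
):
    """Delta matrix + informative indices from a synthetic feature cohort."""
    cfg = dr.CohortConfig(
        n_progressors=n_per_class,
        n_nonprogressors=n_per_class,
        effect_size=effect_size,
        n_features=n_features,
        n_informative=n_informative,
        seed=seed,
    )
    cohort = dr.generate_feature_cohort(cfg)
    dm = dr.delta_matrix(cohort.base, cohort.final, cohort.outcome)
    return dm, cohort.ground_truth


@pytest.fixture(scope="session")
def strong_delta():
    """Well-separated cohort (effect size 2, n=60, 3/20 informative)."""
    return feature_delta(effect_size=2.0, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blob_mask(rng):
    """A random connected-ish 3D blob mask for morphology properties."""
    m = rng.random((10, 10, 8)) < 0.35
    m[3:6, 3:6, 2:5] = True  # solid 3x3x3 core survives opening
    return m
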
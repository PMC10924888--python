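import warnings

import numpy as np
import pandas as pd
import pytest

from rrtuplift import ClassTransformationUplift, SimConfig, generate_cohort
from rrtuplift.matching import DEFAULT_PSM_COVARIATES


def features_of(df: pd.DataFrame) -> list[str]:
    return [c for c in DEFAULT_PSM_COVARIATES if c in df.columns]


@pytest.fixture(scope="session")
def randomized_cohort() -> pd.DataFrame:
    """Randomized (unconfounded) 50/50 cohort with the default
    heterogeneous treatment effect; potential outcomes attached."""
    cfg = SimConfig(n_patients=8000, treat_fraction_target=0.5, confounding_strength=0.0, seed=101)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return generate_cohort(cfg)


@pytest.fixture(scope="session")
def confounded_cohort() -> pd.DataFrame:
    """Default-condition observational cohort: sicker patients treated."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return generate_cohort(SimConfig(n_patients=6000, seed=202))


@pytest.fixture(scope="session")
def fitted_uplift(randomized_cohort):
    """Uplift model fitted on the randomized cohort (arms ~equal)."""
    model = ClassTransformationUplift(randomized_cohort, features_of(randomized_cohort))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return model.fit(seed=101)


def random_qini_instance(rng: np.random.Generator, max_total: int = 30):
    """Small random evaluation instance for brute-force qini checks."""
    n_t = int(rng.integers(1, max_total))
    n_c = int(rng.integers(1, max_total - n_t + 1))
    n = n_t + n_c
    treated = np.array([1] * n_t + [0] * n_c)
    rng.shuffle(treated)
    survived = rng.integers(0, 2, n)
    # coarse scores force plenty of ties
    scores = rng.integers(0, 5, n).astype(float)
    ids = np.arange(n)
    return scores, treated, survived, ids
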
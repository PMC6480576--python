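import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from datquant import (
    PhantomParams,
    feature_table,
    iter_cohort,
    null_separation_params,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: reduced grid that still contains the whole default head geometry;
#: used where full 128x128x64 resolution is not the point
SMALL_GRID = dict(grid_shape=(64, 64, 32))


@pytest.fixture(scope="session")
def default_params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    return PhantomParams(**SMALL_GRID)


@pytest.fixture(scope="session")
def cohort_features(default_params) -> pd.DataFrame:
    """Feature table of the 30/30/30 default-separation phantom cohort."""
    return feature_table(iter_cohort((30, 30, 30), default_params, seed=20220419))


@pytest.fixture(scope="session")
def null_cohort_features(default_params) -> pd.DataFrame:
    """Feature table of a cohort with stage separation disabled."""
    params = null_separation_params(default_params)
    return feature_table(iter_cohort((40, 40, 40), params, seed=9041))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
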
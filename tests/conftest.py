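import numpy as np
import pytest

from gaitsep import (
    StrideSimParams,
    generate_feature_cohort,
    generate_stride_series,
    load_cohort_fixture,
)


@pytest.fixture(scope="session")
def general_cohort():
    """Seeded 483-subject cohort drawn from the general fixture."""
    return generate_feature_cohort(load_cohort_fixture("general"), seed=11)


@pytest.fixture(scope="session")
def noiseless_strides():
    """Eight noiseless strides with planted ground-truth events."""
    params = StrideSimParams(n_strides=8, seed=3)
    series, events = generate_stride_series(params)
    return params, series, events


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
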
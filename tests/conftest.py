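import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from strokexplain import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(seed=123)


@pytest.fixture(scope="session")
def large_cohort(default_spec):
    """n = 50,000 draw from the default spec; shared across marginal tests."""
    from dataclasses import replace

    spec = replace(default_spec, n_subjects=50_000)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def standardized_training_data():
    """A mid-size standardized design matrix with labels from the planted
    model, for model-fitting tests that need realistic inputs."""
    from strokexplain.preprocessing import apply_preprocess, dichotomize_mrs, fit_preprocess

    spec = CohortSpec(n_subjects=2000, missing_rate=0.0, seed=77)
    cohort = generate_cohort(spec)
    state = fit_preprocess(cohort.features)
    X = apply_preprocess(state, cohort.features)
    y = dichotomize_mrs(cohort.mrs)
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
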
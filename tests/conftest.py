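import numpy as np
import pandas as pd
import pytest

from mepx import CohortConfig, ProtocolSpec, build_feature_table, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (8 MDD + 6 HC) for fast stage tests."""
    return generate_cohort(CohortConfig(n_mdd=8, n_hc=6, seed=11))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    features, _ = build_feature_table(small_cohort)
    return features


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-sized cohort (26 MDD + 17 HC), seed fixed."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    features, _ = build_feature_table(default_cohort)
    return features
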
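"""Shared fixtures: a small synthetic cohort and its feature pipeline."""

import numpy as np
import pytest

from eegselect import (
    CohortSpec,
    FeatureConfig,
    MaskFitness,
    SplitConfig,
    generate_cohort,
    split,
)
from eegselect.experiments import cohort_feature_table


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """4 subjects, 8 channels of which {1, 4} are informative."""
    return CohortSpec(
        n_subjects=4,
        n_channels=8,
        informative_channels=frozenset({1, 4}),
        records_per_subject=6,
        record_duration_s=10.0,
        sampling_rate_hz=160.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return cohort_feature_table(small_cohort, FeatureConfig("AR5"))


@pytest.fixture(scope="session")
def small_split(small_table):
    return split(small_table, SplitConfig(seed=11))


@pytest.fixture()
def small_fitness(small_split):
    train, val, _test = small_split
    return MaskFitness(train, val)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
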
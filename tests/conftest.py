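"""Shared fixtures: small seeded cohorts and feature tables.

Session-scoped so the expensive generation runs once per pytest session.
"""

import warnings

import numpy as np
import pytest

from thermosense.cohort import GeneratorConfig, generate_cohort
from thermosense.features import build_feature_table


@pytest.fixture(scope="session")
def compact_config():
    return GeneratorConfig.compact()


@pytest.fixture(scope="session")
def clean_config():
    return GeneratorConfig.compact(corruption_prob=0.0)


@pytest.fixture(scope="session")
def cohort(compact_config):
    """Default 20x8 cohort with corruption, seed 1."""
    return generate_cohort(compact_config, 1)


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    """Corruption-free 20x8 cohort (160 clean trials), seed 11."""
    return generate_cohort(clean_config, 11)


@pytest.fixture(scope="session")
def feature_table(cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_feature_table(cohort)


@pytest.fixture(scope="session")
def clean_feature_table(clean_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_feature_table(clean_cohort, screen=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
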
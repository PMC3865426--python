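"""Shared fixtures: template priors and a segmented control cohort.

The cohort is expensive (12 simulated + segmented controls), so it is
built once per session and shared by the end-to-end tests.
"""

import numpy as np
import pytest

from aliseg import scenarios, with_extra_prior


@pytest.fixture(scope="session")
def conditions():
    return scenarios.default_conditions()


@pytest.fixture(scope="session")
def priors(conditions):
    return scenarios.template_priors(conditions)


@pytest.fixture(scope="session")
def seg_priors(priors):
    return with_extra_prior(priors)


@pytest.fixture(scope="session")
def brain(priors):
    return priors.brain_mask()


@pytest.fixture(scope="session")
def cohort(priors, conditions):
    return scenarios.build_control_cohort(priors, conditions, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
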
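"""Shared fixtures: random SPD sets and synthetic cohorts at two scales.

The full-size cohort (54 participants, 50 regions — the package's standard
study conditions) is session-scoped because several integration tests share
it; the tiny cohort keeps unit-level pipeline tests fast.
"""

import numpy as np
import pytest

from tanrec.reconfig import FunctionalReconfiguration
from tanrec.synthetic import SyntheticConfig, generate_cohort, generate_spd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spd_pair():
    a, b = generate_spd(5, 2, condition_number_cap=50, seed=7)
    return a, b


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = SyntheticConfig(seed=11, n_subjects=10, n_regions=12)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_results(tiny_cohort):
    model = FunctionalReconfiguration.from_cohort(tiny_cohort)
    return model, model.fit()


@pytest.fixture(scope="session")
def default_cohort():
    """The standard study conditions: n=54 participants, p=50 regions."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_results(default_cohort):
    model = FunctionalReconfiguration.from_cohort(default_cohort)
    return model, model.fit(compute_manifold_rates=True)
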
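import numpy as np
import pytest

from brigex import PopPKParameters, apply_covariates_and_eta
from brigex.trial import OutcomeTruth, TrialDesign, simulate_trial


@pytest.fixture(scope="session")
def pop():
    return PopPKParameters.from_yaml()


@pytest.fixture(scope="session")
def typical(pop):
    return apply_covariates_and_eta(pop, pop.alb_ref, np.zeros(5))


@pytest.fixture(scope="session")
def small_trial(pop):
    """A 40-subject virtual trial shared across tests (read-only)."""
    design = TrialDesign(n_subjects=40, max_follow_up_days=730)
    return simulate_trial(design, pop, OutcomeTruth(), seed=42)


@pytest.fixture(scope="session")
def full_trial(pop):
    """Default 123-subject virtual trial (read-only)."""
    return simulate_trial(seed=2024)
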
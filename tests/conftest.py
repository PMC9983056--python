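import numpy as np
import pytest

from jointbin.simulate import StudyConfig, default_truth, run_study, simulate_cohort


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def toy_cohort(truth):
    """Small simulated cohort shared by fast tests."""
    rng = np.random.default_rng(2024)
    return simulate_cohort(truth, 40, rng)


@pytest.fixture(scope="session")
def small_study():
    """Reduced-scale Monte-Carlo study: 30 replicates of N=100 fits.

    Session-scoped because each replicate involves a full marginal-ML
    fit; the parameter-recovery checks all read from this one study.
    """
    cfg = StudyConfig(N=100, n_reps=30, seed=1234, nodes=7)
    return run_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
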
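import numpy as np
import pytest

from dcvdrisk import SimulationSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4000-sample cohort under the default study conditions (K=0.17, h2=0.5,
    bundled 47-SNP panel, four covariates, four cohorts)."""
    return simulate_cohort(SimulationSpec(n_samples=4000, seed=7))


@pytest.fixture(scope="session")
def large_cohort():
    """200k-sample cohort for calibration checks that need tight Monte-Carlo
    error; simulated once per session."""
    return simulate_cohort(SimulationSpec(n_samples=200_000, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
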
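import numpy as np
import pytest

from cirpop import MCMCConfig, simulate_study
from cirpop.model import ChangeInRatioModel


@pytest.fixture(scope="session")
def reference_study():
    """One 20-year simulated study with known truth (drawn detection, with TOT)."""
    rng = np.random.default_rng(7)
    truth, dataset = simulate_study(rng, n_years=20)
    return truth, dataset


@pytest.fixture(scope="session")
def reference_fit(reference_study):
    """A desk-profile M1 fit of the reference study, shared across tests."""
    truth, dataset = reference_study
    result = ChangeInRatioModel(dataset).fit(MCMCConfig.desk(seed=3))
    return truth, dataset, result
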
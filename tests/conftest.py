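import numpy as np
import pytest

from ulvapop import simulate as sim


@pytest.fixture(scope="session")
def unit_spec():
    return sim.SpeciesPanelSpec.unit_scale()


@pytest.fixture(scope="session")
def unit_panel(unit_spec):
    """One realized unit-scale six-species panel, shared across tests."""
    return sim.simulate_panel(unit_spec, seed=11)


@pytest.fixture(scope="session")
def full_panel():
    """Full printed-scale panel (103/80 kb organelles, 5 kb 45S)."""
    return sim.simulate_panel(sim.SpeciesPanelSpec(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
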
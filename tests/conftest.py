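import numpy as np
import pytest

from tdprisk import cell_sim, synth_fixtures


@pytest.fixture(scope="session")
def steady_state():
    """Shipped drug-free steady state (endo, CL 2000 ms, 10,000 beats)."""
    return cell_sim.steady_state()


@pytest.fixture(scope="session")
def drug_free_series(steady_state):
    """Short drug-free paced continuation used by several tests."""
    cfg = cell_sim.CellModelConfig()
    return cell_sim.simulate_drug(steady_state, cfg, n_beats=5)


@pytest.fixture(scope="session")
def surrogate_ds():
    """Separable surrogate AP dataset: 100 traces per risk class."""
    return synth_fixtures.make_surrogate_aps(100, seed=42)


@pytest.fixture(scope="session")
def default_panel():
    return synth_fixtures.default_panel(seed=7)
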
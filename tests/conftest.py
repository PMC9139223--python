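import pytest

from pairrep import SimConfig, default_catalog, simulate_expression, simulate_repertoire


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def sim_medium():
    """A mid-size simulated sample reused across read-only tests."""
    config = SimConfig(n_cells=5000, n_clones=100, seed=11)
    records, truth = simulate_repertoire(config)
    return config, records, truth


@pytest.fixture(scope="session")
def sim_medium_expr(sim_medium):
    config, _, truth = sim_medium
    return simulate_expression(config, truth.cell_ids, truth)
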
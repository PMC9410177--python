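import pytest

from lignanscreen.simulate import (
    SimConfig,
    simulate_expression,
    simulate_pangenome,
    simulate_pinoresinol_profile,
)


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig(rng_seed=0)


@pytest.fixture(scope="session")
def dataset(default_cfg):
    """One fully simulated pan-genome bundle shared across tests."""
    return simulate_pangenome(default_cfg)


@pytest.fixture(scope="session")
def expression(default_cfg, dataset):
    return simulate_expression(default_cfg, dataset.truth)


@pytest.fixture(scope="session")
def kinetic_profile(default_cfg):
    return simulate_pinoresinol_profile(list(default_cfg.stages))
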
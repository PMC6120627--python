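import pytest

from polymethkit.simpanel import (
    SimConfig,
    simulate_expression,
    simulate_genome,
    simulate_panel,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_accessions=8,
        n_populations=2,
        subgenome_length=6000,
        chloroplast_length=3000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_panel(small_cfg, small_genome):
    return simulate_panel(small_cfg, small_genome)


@pytest.fixture(scope="session")
def small_expression(small_cfg, small_panel):
    return simulate_expression(small_cfg, small_panel.truth)
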
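import pytest

from crosspred.popsim import PopSimConfig, simulate_panel
from crosspred.phenosim import partition_candidate_qtl


TINY_CONFIG = dict(
    n_individuals=(120, 50, 60),
    within_pop_ne=(150, 80, 80),
    n_snps_per_chromosome=260,
    divergence_generations=30,
    n_founder_haplotypes=10,
)


@pytest.fixture(scope="session")
def tiny_data():
    """Small three-population dataset shared across tests."""
    return simulate_panel(PopSimConfig(**TINY_CONFIG, seed=42))


@pytest.fixture(scope="session")
def tiny_panel(tiny_data):
    return tiny_data.panel


@pytest.fixture(scope="session")
def tiny_arch(tiny_panel):
    """Candidate/marker partition on the tiny panel (~150 candidates)."""
    return partition_candidate_qtl(tiny_panel, 150, seed=7)


@pytest.fixture(scope="session")
def desk_data():
    """Desk-scale dataset for the heavier model-comparison tests."""
    from crosspred.scenarios import desk_config
    return simulate_panel(desk_config(seed=1))
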
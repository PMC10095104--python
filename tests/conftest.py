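import pandas as pd
import pytest

from xenotx import SimConfig, simulate_two_pass_counts


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale configuration used across tests (study-regime ratios)."""
    return SimConfig(
        n_genes_orth=300,
        n_genes_private_hs=20,
        n_genes_private_mm=20,
        n_samples_per_group=4,
        n_nodes=40,
        genes_per_node=10,
        seed=101,
    )


@pytest.fixture(scope="session")
def two_pass(small_cfg):
    """(hs, mm, orth, truth) from one generator run."""
    return simulate_two_pass_counts(small_cfg)
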
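import pytest

from amplifam import SimConfig, simulate_ccs_reads, simulate_repertoire


@pytest.fixture(scope="session")
def small_sim():
    """Small zero-error, zero-chimera simulation with full truth."""
    config = SimConfig(
        seed=3,
        n_loci_per_subfamily=8,
        reads_per_individual=600,
        eps1=0.0,
        chimera_fraction=0.0,
        pseudogene_fraction=0.0,
    )
    truth = simulate_repertoire(config)
    reads = simulate_ccs_reads(truth, config)
    return config, truth, reads


@pytest.fixture(scope="session")
def noisy_sim():
    """Small simulation with the default error model."""
    config = SimConfig(
        seed=5,
        n_loci_per_subfamily=6,
        reads_per_individual=400,
        eps1=0.02,
        chimera_fraction=0.0,
        pseudogene_fraction=0.0,
    )
    truth = simulate_repertoire(config)
    reads = simulate_ccs_reads(truth, config)
    return config, truth, reads
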
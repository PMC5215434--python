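import pytest

from ubiqevo import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """12-protein bundle with planted gains, shared across read-only tests."""
    config = SimulationConfig(
        n_proteins=12,
        protein_length_range=(80, 140),
        sites_per_protein=2,
        planted_gain_epochs={"vertebrate": 4, "eukaryote": 4},
        seed=42,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def tiny_bundle():
    """3-protein bundle for serialization round-trip tests."""
    config = SimulationConfig(
        n_proteins=3,
        protein_length_range=(60, 90),
        sites_per_protein=2,
        indel_rate=0.002,
        missing_ortholog_rate=0.1,
        seed=7,
    )
    return simulate_dataset(config)
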
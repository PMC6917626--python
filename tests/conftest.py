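import pytest

from biocode.synthetic_data import SimulationConfig, generate_world


@pytest.fixture(scope="session")
def clean_world():
    """Noise-free world: no contamination, no sequencing error, no dropout."""
    cfg = SimulationConfig(
        n_species=5,
        specimens_per_species=2,
        reads_per_specimen_mean=120,
        per_base_error=0.0,
        contamination_fraction=0.0,
        seed=11,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def noisy_world():
    """Small world with contamination and sequencing error at realistic rates."""
    cfg = SimulationConfig(
        n_species=6,
        specimens_per_species=3,
        reads_per_specimen_mean=150,
        per_base_error=0.001,
        contamination_fraction=0.1,
        seed=3,
    )
    return generate_world(cfg)
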
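import pytest
from hypothesis import settings

from strandtag import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_config() -> sd.SynthConfig:
    """Study conditions with error-free counting (no antisense/singleton noise)."""
    return sd.SynthConfig(
        seed=101,
        antisense_error_rate=0.0,
        singleton_fraction=0.0,
        unaligned_fraction=0.0,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    """Genome + truth + both libraries under the clean config (shared, read-only)."""
    sequences, truth = sd.generate_genome(clean_config)
    polya = sd.simulate_library(sequences, truth, "polyA", clean_config)
    ribozero = sd.simulate_library(sequences, truth, "ribozero", clean_config)
    return sequences, truth, polya, ribozero
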
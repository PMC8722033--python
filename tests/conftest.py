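import pytest
from hypothesis import settings

from prenataldx import synthdata as sd

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_model() -> sd.GenomeModel:
    return sd.build_genome_model(sd.SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def small_cohort(default_model) -> sd.TrioCohort:
    return sd.simulate_trio_cohort(default_model, n_trios=40, seed=11)
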
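import numpy as np
import pytest

from sdpanpop.io_formats import PopulationLabels
from sdpanpop.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig.small()


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config, seed=11)


@pytest.fixture()
def toy_labels() -> PopulationLabels:
    """3 samples (1 AFR, 2 non-AFR), two haplotypes each."""
    sample_of = {f"S{i}_h{h}": f"S{i}" for i in range(3) for h in (1, 2)}
    superpop = {"S0": "AFR", "S1": "non-AFR", "S2": "non-AFR"}
    pop = {s: "x" for s in superpop}
    return PopulationLabels(sample_of, superpop, pop)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)
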
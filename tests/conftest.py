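import numpy as np
import pytest

from promusage.annotation import derive_first_exons
from promusage.simulate import SimConfig, simulate_gene_model


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(reads_per_sample=2000, seed=11)


@pytest.fixture(scope="session")
def gene_model(sim_cfg):
    return simulate_gene_model(sim_cfg)


@pytest.fixture(scope="session")
def first_exons(gene_model):
    return derive_first_exons(gene_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
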
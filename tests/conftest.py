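import numpy as np
import pytest

from famet import SimConfig, simulate_dataset
from famet.kernels import additive_kernel, epistatic_kernel, stabilize


@pytest.fixture(scope="session")
def small_dataset():
    """A small but realistic trial: 60 inbred lines, 3 sites, 2 reps."""
    cfg = SimConfig(n_genotypes=60, n_markers=300, n_sites=3, seed=11)
    markers, truth, pheno = simulate_dataset(cfg)
    return cfg, markers, truth, pheno


@pytest.fixture(scope="session")
def small_kernels(small_dataset):
    _, markers, _, _ = small_dataset
    g_a = stabilize(additive_kernel(markers))
    g_aa = stabilize(epistatic_kernel(additive_kernel(markers)))
    return g_a, g_aa


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
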
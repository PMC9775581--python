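import numpy as np
import pytest

from omnifuse import OmicsMatrix, SimConfig, simulate_multiomics
from omnifuse.clustering import PartitionLabels


@pytest.fixture(scope="session")
def default_sim():
    """One draw of the generator at its default study conditions."""
    cfg = SimConfig(seed=1)
    rna, meth, truth = simulate_multiomics(cfg)
    return cfg, rna, meth, truth


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down draw for fast unit tests."""
    cfg = SimConfig(
        n_samples=60,
        rna_n_genes=300,
        rna_n_informative=60,
        meth_n_probes=400,
        meth_n_informative=80,
        seed=3,
    )
    rna, meth, truth = simulate_multiomics(cfg)
    return cfg, rna, meth, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(values, domain="test", prefix="s"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsMatrix(
        [f"{prefix}{i:03d}" for i in range(n)],
        [f"f{j:04d}" for j in range(p)],
        values,
        domain=domain,
    )


def make_partition(labels):
    labels = np.asarray(labels, dtype=int)
    return PartitionLabels([f"s{i:03d}" for i in range(labels.size)], labels, int(labels.max()))
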
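import numpy as np
import pytest

from molfm.molgraph import Vocabulary
from molfm.network import Denoiser, NetworkConfig
from molfm.toydata import ToyDatasetConfig, generate_fixtures


@pytest.fixture(scope="session")
def vocab():
    return Vocabulary()


@pytest.fixture(scope="session")
def fixture_set():
    """The full synthetic fixture set (seeded, deterministic)."""
    return generate_fixtures(ToyDatasetConfig(seed=0))


@pytest.fixture(scope="session")
def small_fixtures(fixture_set):
    """A handful of small fixture molecules for fast graph-level tests."""
    return [g for g in fixture_set.graphs if g.n_atoms <= 9]


@pytest.fixture(scope="session")
def tiny_model(vocab):
    """An untrained denoiser small enough for contract tests."""
    cfg = NetworkConfig(n_blocks=2, scalar_dim=24, vector_dim=4, edge_dim=12,
                        rbf_count=8, rbf_max=8.0)
    return Denoiser(cfg, vocab, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
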
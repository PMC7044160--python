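import numpy as np
import pytest

from silencerscan.synth import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down synthetic study used by several module tests."""
    return SynthConfig(
        seed=7,
        n_genes=25,
        n_enhancers=50,
        n_ctcf=40,
        n_ucres=200,
        n_tested=200,
        n_interactions=80,
        n_traits=4,
        snps_per_trait=40,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_dataset(small_config)
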
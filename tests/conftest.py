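import numpy as np
import pytest

from plasmidess import PangenomeConfig, generate_pangenome


@pytest.fixture(scope="session")
def small_pangenome():
    """A compact pangenome with planted ground truth, shared across tests."""
    cfg = PangenomeConfig(n_isolates=8, n_families=40, n_core_essential=8,
                          n_chromosome_filler=3, p_essential=0.05, seed=2)
    return generate_pangenome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
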
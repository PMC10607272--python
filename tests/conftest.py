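import numpy as np
import pytest

from hzkit.synth import PedigreeScenario, ZoneScenario, simulate_pedigree, simulate_zone


@pytest.fixture(scope="session")
def zone():
    """Default simulated hybrid zone (150 individuals, 40 diag + 400 bg loci)."""
    return simulate_zone(ZoneScenario(seed=1))


@pytest.fixture(scope="session")
def pedigree():
    """All eight pedigree classes, 100 individuals each, 100 diagnostic loci."""
    return simulate_pedigree(PedigreeScenario(n_per_class=100, n_diag_loci=100, seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
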
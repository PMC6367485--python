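import numpy as np
import pytest

from coreshell import DLSConfig, ParticlePopulation, gen_afm_topograph

DEFAULT_TAUS = np.logspace(-7, -1, 200)


@pytest.fixture(scope="session")
def dls_config():
    return DLSConfig()


@pytest.fixture(scope="session")
def taus():
    return DEFAULT_TAUS


@pytest.fixture(scope="session")
def sphere_topograph():
    """One noiseless 50-nm sphere on a flat 200-nm field, 1-nm pixels."""
    pop = ParticlePopulation([50.0], label="sphere")
    topo, truth = gen_afm_topograph(pop, pixel_nm=1.0, field_nm=200.0, seed=5)
    return topo, truth


@pytest.fixture(scope="session")
def oblate_topograph():
    """One noiseless oblate spheroid, width/height = 1.728."""
    pop = ParticlePopulation([100.0], label="oblate")
    topo, truth = gen_afm_topograph(pop, pixel_nm=1.0, field_nm=400.0,
                                    shape_aspect=1.728, seed=6)
    return topo, truth
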
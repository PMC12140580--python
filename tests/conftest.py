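import numpy as np
import pytest

from dynmod.connectivity import MultilayerNetwork, WindowSpec
from dynmod.synthetic import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Tiny cohort for fast end-to-end tests."""
    return CohortConfig(
        n_subjects=4,
        n_regions=16,
        n_volumes=96,
        n_modules_planted=2,
        subgroup_sizes={"FF": 2, "SS": 1, "SF": 1},
        seed=11,
    )


def random_multilayer(rng, n_layers=2, n_regions=6, density=0.5):
    """Random sparse symmetric multislice network for oracle tests."""
    layers = np.zeros((n_layers, n_regions, n_regions))
    for l in range(n_layers):
        a = np.triu(rng.random((n_regions, n_regions)), 1)
        a[a < 1 - density] = 0
        layers[l] = a + a.T
    return MultilayerNetwork(
        layers=layers, window=WindowSpec(4, 4), band=(0.125, 0.25)
    )


@pytest.fixture
def make_net(rng):
    def _make(**kw):
        return random_multilayer(rng, **kw)

    return _make
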
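import warnings

import numpy as np
import pytest

from orthotyper.synthetic import SimulationConfig, simulate_atlas

warnings.filterwarnings("ignore", category=UserWarning, module="scanpy")
warnings.filterwarnings("ignore", message=".*densifies.*")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_atlas():
    """Two species, two classes, three planted types per class."""
    cfg = SimulationConfig(
        seed=7,
        n_species=2,
        classes={"BC": 30, "RGC": 30},
        types_per_class=3,
        cells_per_type=40,
        n_genes=1000,
        markers_per_type=15,
    )
    return simulate_atlas(cfg)


@pytest.fixture(scope="session")
def six_class_atlas():
    """Two species with all six retinal classes planted."""
    cfg = SimulationConfig(
        seed=2,
        n_species=2,
        types_per_class=3,
        cells_per_type=60,
        n_genes=1500,
        markers_per_type=20,
    )
    return simulate_atlas(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
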
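import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from doublemesh.geometry import DetectorGeometry
from doublemesh.simulate import SimulationConfig, render_double_mesh


@pytest.fixture(scope="session")
def detector() -> DetectorGeometry:
    return SimulationConfig().detector


@pytest.fixture(scope="session")
def small_sim():
    """A small, fully deterministic 3-crystal double mesh scan."""
    cfg = SimulationConfig(n_crystals=3, seed=11, omegas=(0.0, 60.0))
    scan1, scan2, truth = render_double_mesh(cfg)
    return cfg, scan1, scan2, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
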
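import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from morphokaryo import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic dataset shared by read-only tests."""
    return simulate_dataset(SimulationParams(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_shapes(rng, n, k, scale=0.05):
    """Random landmark configurations: template + small iid perturbations."""
    ang = np.linspace(0, 2 * np.pi, k, endpoint=False)
    template = np.column_stack([np.cos(ang), 0.7 * np.sin(ang)])
    return template[None] + scale * rng.standard_normal((n, k, 2))
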
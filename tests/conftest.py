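import numpy as np
import pytest

from morphomotion import SimulationParams, make_shell, simulate_cohort
from morphomotion.io import VoxelVolume, cohort_to_frame


@pytest.fixture(scope="session")
def cohort_frame():
    """One default synthetic cohort (n=640) as a DataFrame."""
    return cohort_to_frame(simulate_cohort(SimulationParams(n_subjects=640, seed=11)))


@pytest.fixture(scope="session")
def shell_volume():
    """Scalar-valued hollow-shell phantom used by the edge-strength tests."""
    shell = make_shell(10, 2)
    return VoxelVolume(data=np.asarray(shell.data, dtype=float) * 100.0)


@pytest.fixture()
def step_slice():
    """16x16 slice: left half 0, right half 1 (unit step along columns)."""
    sl = np.zeros((16, 16))
    sl[:, 8:] = 1.0
    return sl


def random_binary_volume(rng, max_edge=20, density=0.3):
    shape = tuple(rng.integers(4, max_edge + 1, size=3))
    return VoxelVolume(data=(rng.random(shape) < density).astype(np.uint8))
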
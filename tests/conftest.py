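import numpy as np
import pytest
from hypothesis import settings

from vsimri import PhantomSpec, PhysicsConfig, SimulationConfig, make_brain_phantom

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def physics() -> PhysicsConfig:
    """Study physics: 7 T, CGS susceptibility difference 4.5e-7."""
    return PhysicsConfig()


@pytest.fixture(scope="session")
def tiny_sim() -> SimulationConfig:
    """Small Monte Carlo profile for fast unit tests."""
    return SimulationConfig(grid_dims=(48, 48, 48), n_walkers=5000, n_reps=2, seed=0)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Half-scale brain phantom for fast tests (same tissue values)."""
    return PhantomSpec(
        grid_dims=(48, 48, 24),
        semi_axes=(20.0, 16.0, 10.0),
        lesion_center=(15.0, 24.0, 12.0),
        lesion_radius=5.0,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return make_brain_phantom(small_spec)
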
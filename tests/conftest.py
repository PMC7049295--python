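import numpy as np
import pytest

from swarmqs.synthetic_tracks import TrackGenSpec, generate_library
from swarmqs.trajectory_stats import extract_kinematics


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_heterogeneous_library():
    """A compact library with persistent and diffusive subpopulations."""
    spec = TrackGenSpec(
        agent_kind="nanobeads",
        n_tracks=24,
        duration=6.0,
        frame_interval=0.07,
        speed_mean=23.4,
        speed_sd=10.0,
        turn_sd=606.0,
        persistence_mixture=[(0.5, 0.7, 0.7), (0.5, 1.1)],
        seed=42,
    )
    lib = generate_library(spec)
    for t in lib.tracks:
        extract_kinematics(t)
    return lib


@pytest.fixture(scope="session")
def zero_drift_isotropic_library():
    """A library with purely diffusive, unbiased tracks."""
    spec = TrackGenSpec(
        agent_kind="nanobeads",
        n_tracks=20,
        duration=6.0,
        frame_interval=0.07,
        speed_mean=20.0,
        speed_sd=5.0,
        turn_sd=500.0,
        persistence_mixture=[(1.0, 1.0)],
        seed=7,
    )
    lib = generate_library(spec)
    for t in lib.tracks:
        extract_kinematics(t)
    return lib
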
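import numpy as np
import pytest

from synapse4d import ImagingParams, make_preset, simulate_population
from synapse4d.render import render_movie


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale movie geometry used across rendered-fixture tests."""
    return ImagingParams(
        voxel_size_xyz=(0.4, 0.4, 0.9),
        frame_interval=10.0,
        n_frames=60,
        volume_shape=(9, 56, 56),
        channel_names=("actin", "target", "centrosome", "calcium"),
    )


@pytest.fixture(scope="session")
def docked_truth(small_params):
    """One N4 conjugate whose centrosome docks well inside the movie."""
    preset = make_preset("N4", docking_time_dist=type(
        make_preset("N4").docking_time_dist)(300.0, 0.1))
    truths = simulate_population(preset, 4, small_params.duration,
                                 rng_seed=123, mode="docked")
    # pick one docking early enough to observe the docked plateau
    return min(truths, key=lambda t: t.docking_time_s or np.inf)


@pytest.fixture(scope="session")
def noisefree_docked_movie(small_params, docked_truth):
    return render_movie([docked_truth], small_params, rng_seed=7, noise=False)


@pytest.fixture(scope="session")
def noisy_docked_movie(small_params, docked_truth):
    return render_movie([docked_truth], small_params, rng_seed=7, noise=True)
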
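import numpy as np
import pytest

from streakdyn import synthetic as syn


@pytest.fixture(scope="session")
def hazard_tracks():
    """2000 non-dividing tracks under a uniform 0.05/frame ingression hazard."""
    params = syn.TrackGenParams(
        n_cells=2000,
        duration=120.0,
        frame_interval=4.0,
        convergence_profile=0.0,
        node_speed=0.0,
        ingression_hazard_profile=0.05,
        seed=5,
    )
    return syn.generate_tracks(params)


@pytest.fixture(scope="session")
def gradient_tracks():
    """2000 tracks with a linear AP convergence gradient (v_LM = 0.002 y + 0.2)."""
    params = syn.TrackGenParams(
        n_cells=2000,
        duration=60.0,
        frame_interval=4.0,
        node_speed=1.0,
        convergence_profile=lambda y: 0.002 * np.asarray(y) + 0.2,
        position_noise_sd=1.0,
        seed=6,
    )
    return syn.generate_tracks(params), 0.002


@pytest.fixture(scope="session")
def five_clone_colors():
    """Five well-separated clones (hue noise 0.03), no ambiguous cells."""
    params = syn.CloneGenParams(
        n_clones=5, cells_per_clone=40, hue_noise_sd=0.03, seed=3
    )
    return syn.generate_clone_colors(params)


@pytest.fixture(scope="session")
def mixture_colors():
    """Five tight clones plus 50 uniform-hue ambiguous cells."""
    params = syn.CloneGenParams(
        n_clones=5, cells_per_clone=40, hue_noise_sd=0.03, n_ambiguous=50, seed=3
    )
    return syn.generate_clone_colors(params)
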
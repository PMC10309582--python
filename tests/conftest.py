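import numpy as np
import pytest

from declutter import SimConfig, simulate_movie, simulate_traces


@pytest.fixture(scope="session")
def trace_sim():
    """Desk-scale three-archetype trace simulation with ground truth."""
    config = SimConfig(n_cells=30, n_frames=120, stimulus_frame=30, seed=5)
    traces, truth = simulate_traces(config)
    return config, traces, truth


@pytest.fixture(scope="session")
def movie_sim():
    """Noise-controlled synthetic movie with 30 somata and truth layers."""
    config = SimConfig(
        n_cells=30, n_frames=40, stimulus_frame=10, height=192, width=192,
        seed=7, noise_sd=0.02,
    )
    return config, simulate_movie(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
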
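"""Shared fixtures: small synthetic movies generated at test time."""

import numpy as np
import pytest

import motrack
from motrack.synth import SynthParams, generate_movie


@pytest.fixture(scope="session")
def small_movie():
    """10 cells, 15 frames, 320 px field — quick but fully featured."""
    params = SynthParams(n_cells=10, n_frames=15, field_size_px=320, seed=5)
    truth, channels = generate_movie(params)
    return params, truth, channels


@pytest.fixture(scope="session")
def small_pipeline(small_movie):
    """Full pipeline run on the small movie (in memory)."""
    params, truth, channels = small_movie
    config = motrack.RunConfig(calibration=params.calibration)
    result = motrack.run_pipeline(config, channels=channels)
    return params, truth, channels, result


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
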
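"""Shared fixtures: small, fast synthetic scenes with known ground truth."""

import numpy as np
import pytest

from colonyttc.schedule import make_schedule
from colonyttc.synthetic import SimulationParams, simulate_movie


@pytest.fixture(scope="session")
def tiny_noise_free():
    """Noise-free 36-h movie, 12-h cycles, small frame: exact expectations.

    The colony edge advances 1.5 px per frame so birth times are
    frame-resolved; agar_sd = noise_sd = 0 makes the threshold exact.
    """
    params = SimulationParams(
        image_size=(235, 235),
        radial_speed=3.0,
        agar_sd=0.0,
        noise_sd=0.0,
        seed=7,
    )
    schedule = make_schedule(12.0, 0.5, 36.0, temp_light=25.0, temp_dark=23.0)
    stack, truth = simulate_movie(params, schedule)
    return params, schedule, stack, truth


@pytest.fixture(scope="session")
def tiny_noisy():
    """Same scene with the standard noise levels."""
    params = SimulationParams(image_size=(235, 235), radial_speed=3.0, seed=11)
    schedule = make_schedule(12.0, 0.5, 36.0, temp_light=25.0, temp_dark=23.0)
    stack, truth = simulate_movie(params, schedule)
    return params, schedule, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
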
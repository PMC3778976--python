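import numpy as np
import pandas as pd
import pytest

from trackosc.design import generate_design, generate_rts, RTGenParams
from trackosc.forward import make_sensor_array
from trackosc.simulate import EnvelopeParams, default_sources, simulate_epochs


@pytest.fixture(scope="session")
def sensors24():
    return make_sensor_array(24)


@pytest.fixture(scope="session")
def sensors80():
    return make_sensor_array(80)


@pytest.fixture(scope="session")
def small_design():
    """One subject, one block, one repetition: 12 trials, all conditions."""
    return generate_design(n_subjects=1, n_blocks=1, reps_per_condition=1,
                           seed=11)


@pytest.fixture(scope="session")
def rt_design():
    d = generate_design(n_subjects=4, n_blocks=2, reps_per_condition=4, seed=5)
    return generate_rts(d, RTGenParams(), seed=5)


@pytest.fixture(scope="session")
def small_epochs(sensors24, small_design):
    """Response-required trials of one subject at 100 Hz, default sources."""
    resp = small_design[small_design["R"] != 0].reset_index(drop=True)
    return simulate_epochs(resp, default_sources(EnvelopeParams()),
                           sensors=sensors24, fs=100.0, noise_sd=0.5, seed=21)
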
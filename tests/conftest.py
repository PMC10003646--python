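"""Shared fixtures: stimulus trains and simulated sessions.

Session-scoped so the expensive full-scale simulations (4 stimuli x 2
polarities x 500 trials) are built once and reused across test modules.
"""

import numpy as np
import pytest

from ffrdeconv.adaptation import AdaptationParams
from ffrdeconv.pipeline import stimulus_pulse_trains
from ffrdeconv.preprocess import average_responses
from ffrdeconv.simulate import GroundTruthConfig, simulate_session


@pytest.fixture(scope="session")
def tone_set():
    """(trains, stimuli, contours) for the four tones, peak-pressure events."""
    return stimulus_pulse_trains()


@pytest.fixture(scope="session")
def trains(tone_set):
    return tone_set[0]


@pytest.fixture(scope="session")
def default_session(trains):
    """Full-scale session with an onset response, no adaptation, no TFS."""
    cfg = GroundTruthConfig(seed=42)
    epochs, gt = simulate_session(cfg, trains)
    return epochs, gt


@pytest.fixture(scope="session")
def default_avg(default_session):
    return average_responses(default_session[0])


@pytest.fixture(scope="session")
def adapted_session(trains):
    """Full-scale session generated with short-term adaptation (U=0.4, tau=60)."""
    cfg = GroundTruthConfig(seed=7,
                            adaptation=AdaptationParams(U=0.4, tau_ms=60.0))
    epochs, gt = simulate_session(cfg, trains)
    return epochs, gt


@pytest.fixture(scope="session")
def adapted_avg(adapted_session):
    return average_responses(adapted_session[0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
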
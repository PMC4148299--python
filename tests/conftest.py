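import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import boldretest as bt
from boldretest.design import PipelineSpec
from boldretest.runner import _fit_run

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SMALL_SHAPE = (12, 12, 8)


@pytest.fixture(scope="session")
def small_geometry():
    return bt.default_geometry(shape=SMALL_SHAPE)


@pytest.fixture(scope="session")
def schedule():
    return bt.make_paradigm(7)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-only config: no confound, no HRF jitter (correctly specified model)."""
    return bt.SimulationConfig(
        n_subjects=3,
        physio_amplitude=0.0,
        hrf_latency_sd=0.0,
        hrf_latency_session_sd=0.0,
        hrf_dispersion_sd=0.0,
        hrf_dispersion_session_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_run(small_geometry, schedule, clean_config):
    return bt.simulate_session(small_geometry, schedule, clean_config, 0, 1)


@pytest.fixture(scope="session")
def clean_fit(small_geometry, schedule, clean_run):
    return _fit_run(
        clean_run, small_geometry, schedule, PipelineSpec.from_name("default"), 128.0
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
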
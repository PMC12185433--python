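import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_kernel():
    from catrans import TransientKernel
    return TransientKernel()


@pytest.fixture
def small_movie():
    """Tiny no-motion movie with 2 well-separated cells, plus its spec."""
    from catrans import SessionSpec, simulate_movie
    spec = SessionSpec(n_cells=2, rate_per_window=(20.0,), n_frames=150,
                      noise_sd=0.0, drift_amplitude=0.0, seed=42)
    movie, gt = simulate_movie(spec, height=96, width=96, background=0.0)
    return movie, gt, spec
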
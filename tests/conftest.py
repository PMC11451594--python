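import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ou_movie():
    """One medium-length fluctuating-envelope movie shared across tests."""
    from nucleomech import SimConfig
    from nucleomech.simulate import gen_boundary_movie

    cfg = SimConfig(seed=11)
    movie, truth = gen_boundary_movie(cfg, n_angles=16, n_frames=400,
                                      sigma=0.1, tau=1.0)
    return movie, truth
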
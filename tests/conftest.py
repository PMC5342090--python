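import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160922)


@pytest.fixture(scope="session")
def small_phantom():
    """One small-but-realistic phantom pair used by several test modules."""
    from radrepro import PhantomConfig, generate_phantom, perturb_rescan

    config = PhantomConfig(
        grid_shape=(48, 48, 12),
        tumor_radius_mm=12.0,
        rescan_shift_mm=0.5,
        seed=7,
    )
    scan1, mask1 = generate_phantom(config, seed=7)
    scan2, mask2 = perturb_rescan((scan1, mask1), config, seed=7)
    return config, scan1, mask1, scan2, mask2
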
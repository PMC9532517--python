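import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim_config():
    """Compact image conditions for fast unit tests (acceptance uses defaults)."""
    from synquant.simulate import SimConfig

    return SimConfig(
        image_shape=(512, 512),
        n_branches=4,
        branch_length_range=(25.0, 40.0),
        true_density=0.25,
        seed=11,
    )


@pytest.fixture(scope="session")
def rendered_small(small_sim_config):
    from synquant.simulate import generate_neuron_image

    return generate_neuron_image(small_sim_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
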
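import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from densfx.phantoms import PhantomSpec, easy_base_spec, generate_case, generate_cohort


@pytest.fixture(scope="session")
def easy_cohort():
    """60-case low-noise separable cohort shared by the pipeline tests."""
    return generate_cohort(60, base_spec=easy_base_spec(32), seed=7)


@pytest.fixture(scope="session")
def fracture_case():
    """One deterministic fractured phantom at desk scale."""
    spec = dataclasses.replace(
        easy_base_spec(32), fracture_present=True, fracture_angle=0.2, seed=3
    )
    return generate_case(spec)


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free phantom (exact intensity plateaus) without fracture."""
    spec = PhantomSpec(
        grid_size=32,
        voxel_spacing=(1.0, 1.0, 1.0),
        background_hu=(40.0, 0.0),
        dens_radius=5.0,
        dens_height=14.0,
        noise_sd=0.0,
        z_blur_sd=0.0,
        seed=1,
    )
    return generate_case(spec)
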
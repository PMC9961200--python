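import numpy as np
import pytest

from nanopierce.synth import CurveGenParams


@pytest.fixture
def pyramid_params():
    """A pyramidal-tip acquisition with moderate noise."""
    return CurveGenParams(
        membrane_slope=3.0,
        penetration_probability=1.0,
        insertion_force_mean=2.0,
        insertion_force_sd=0.3,
        noise_sd=0.02,
        seed=11,
    )


@pytest.fixture
def sphere_params():
    """A spherical-tip stiffness acquisition (no penetration)."""
    return CurveGenParams(
        cell_modulus=1000.0,
        penetration_probability=0.0,
        insertion_force_mean=1.0,
        noise_sd=0.0,
        trigger_force=2.0,
        spring_constant=0.05,
        tip_kind="sphere",
        tip_radius=2.25,
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
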
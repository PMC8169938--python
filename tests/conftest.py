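import numpy as np
import pytest

from liebauflow.physics import (
    CompressionProtocol,
    FluidProperties,
    TubeGeometry,
)
from liebauflow.scene import SceneConfig


@pytest.fixture
def tygon():
    """The 3-mm-ID observation tube the particles are imaged in."""
    return TubeGeometry(segment_length=0.038, inner_diameter=3e-3, wall_thickness=0.5e-3)


@pytest.fixture
def compliant_segment():
    """The 38-mm, 5-mm-ID compliant segment used in the sweep experiments."""
    return TubeGeometry(segment_length=0.038, inner_diameter=5e-3, wall_thickness=0.5e-3)


@pytest.fixture
def water():
    return FluidProperties(density=1000.0, dynamic_viscosity=0.95e-3)


@pytest.fixture
def protocol_25hz():
    return CompressionProtocol(time_on=0.2, time_off=0.2)


def small_scene(geom, fluid, protocol, **overrides):
    """A short clip with few particles; fast enough for unit tests."""
    defaults = dict(
        geometry=geom,
        fluid=fluid,
        protocol=protocol,
        target_mean_flowrate=15.0,
        clip_duration=2.0,
        n_clips=1,
        particle_density=4.0,
        rng_seed=11,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
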
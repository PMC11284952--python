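import numpy as np
import pytest
from shapely.geometry import Point

from timetopo import PipelineConfig, generate_archetype
from timetopo.zoning import build_zones


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def circle_zones():
    """Zones from a circular tumor field r=1000 µm: closed-form areas known."""
    circle = Point(0.0, 0.0).buffer(1000.0, quad_segs=256)
    return build_zones([circle])


@pytest.fixture(scope="session")
def infiltrated_specimen():
    """One fully-infiltrated synthetic resection, shared across tests."""
    return generate_archetype("fully_infiltrated", seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
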
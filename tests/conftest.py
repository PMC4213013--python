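import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from leatherback import presets
from leatherback.meshes import turtle_mesh

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def neonate_program():
    return presets.stroke_program("neonate")


@pytest.fixture(scope="session")
def juvenile_program():
    return presets.stroke_program("juvenile", bpm=19)


@pytest.fixture(scope="session")
def small_mesh():
    """A coarse flipper+body mesh, enough resolution for integral checks."""
    return turtle_mesh(n_span=8, n_chord=5, body_subdivisions=1)


@pytest.fixture(scope="session")
def metabolic_model():
    return presets.metabolic_model()


@pytest.fixture(scope="session")
def materials():
    return presets.materials()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140429)
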
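import numpy as np
import pytest
from hypothesis import settings

from ivtpk.geometry import build_eye_geometry
from ivtpk.meshing import generate_mesh

settings.register_profile("ci", derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rabbit_geometry():
    return build_eye_geometry("rabbit")


@pytest.fixture(scope="session")
def human_geometry():
    return build_eye_geometry("human")


@pytest.fixture(scope="session")
def rabbit_mesh_coarse(rabbit_geometry):
    """Coarse rabbit mesh for fast unit tests (~a few thousand cells)."""
    return generate_mesh(rabbit_geometry, element_size=1.5e-3, seed=0)


@pytest.fixture(scope="session")
def human_mesh_coarse(human_geometry):
    return generate_mesh(human_geometry, element_size=1.6e-3, seed=0)


@pytest.fixture(scope="session")
def rabbit_mesh_default(rabbit_geometry):
    """Default-resolution rabbit mesh (the production setting)."""
    return generate_mesh(rabbit_geometry, seed=0)
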
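import pytest

from vectornav.geomag import FieldModelConfig
from vectornav.synth import generate_study


@pytest.fixture(scope="session")
def field_cfg():
    return FieldModelConfig()


@pytest.fixture(scope="session")
def dipole_cfg():
    return FieldModelConfig(model="axial_dipole")


@pytest.fixture(scope="session")
def study_records():
    """One synthetic study dataset shared across tests (fixed seed)."""
    return generate_study(7)
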
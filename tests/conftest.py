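import pytest
from hypothesis import HealthCheck, settings

import recuerda as rc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def kb():
    return rc.default_kb()


@pytest.fixture(scope="session")
def schema():
    return rc.default_schema()


@pytest.fixture(scope="session")
def profile():
    return rc.generate_profile(1)


@pytest.fixture()
def patricia_profile(schema):
    """The worked personalization example: first relative Patricia, a daughter."""
    return rc.build_profile(
        schema,
        {"patient_name": "María"},
        [rc.FamilyMember(index=1, name="Patricia", relationship="hija")],
        patient_id="pwad-maria",
    )


@pytest.fixture()
def store(tmp_path):
    return rc.ProfileStore(tmp_path / "store")
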
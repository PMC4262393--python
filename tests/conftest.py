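import pytest
from hypothesis import settings

from sevtier import (
    load_characteristic_summaries,
    load_default_characteristics,
    load_disease_summaries,
    load_packaged_tier_map,
    load_reference_diseases,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def characteristics():
    return load_default_characteristics()


@pytest.fixture(scope="session")
def characteristic_summaries():
    return load_characteristic_summaries()


@pytest.fixture(scope="session")
def packaged_tier_map():
    return load_packaged_tier_map()


@pytest.fixture(scope="session")
def reference_diseases():
    return load_reference_diseases()


@pytest.fixture(scope="session")
def disease_summaries():
    return load_disease_summaries()


@pytest.fixture(scope="session")
def survey_groups(reference_diseases):
    return {d.profile.disease_id: d.survey_group for d in reference_diseases}
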
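import pytest

from waly.catalogue import packaged_catalogue, packaged_disease_models, packaged_life_table
from waly.survey import encode_paired_design, filter_responses
from waly.synthetic import build_scenario


@pytest.fixture(scope="session")
def catalogue():
    return packaged_catalogue()


@pytest.fixture(scope="session")
def diseases(catalogue):
    return packaged_disease_models(catalogue)


@pytest.fixture(scope="session")
def life_table():
    return packaged_life_table()


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic survey (61 respondents, plan 16/16/29), seed 0."""
    return build_scenario(seed=0)


@pytest.fixture(scope="session")
def filtered(scenario):
    return filter_responses(scenario.paired, scenario.anchors)


@pytest.fixture(scope="session")
def design(scenario, filtered):
    return encode_paired_design(filtered.paired, scenario.catalogue)
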
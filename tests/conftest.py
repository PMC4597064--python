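import pytest

from omiclone.fixtures import FixtureConfig, example_case_bundle, generate_bundle


@pytest.fixture(scope="session")
def presentation():
    return example_case_bundle("presentation")


@pytest.fixture(scope="session")
def relapse():
    return example_case_bundle("relapse")


@pytest.fixture(scope="session")
def sim_bundle():
    return generate_bundle(FixtureConfig(seed=7, n_variants=60))
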
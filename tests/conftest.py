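import pytest
from hypothesis import settings

from edit_heritage import generate_target

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def plus_site():
    return generate_target(0.30, amplicon_length=300, strand="plus", seed=101, site_id="plus_site")


@pytest.fixture(scope="session")
def minus_site():
    return generate_target(0.60, amplicon_length=300, strand="minus", seed=202, site_id="minus_site")
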
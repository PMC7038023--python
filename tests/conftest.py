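import pytest

from waterhealth.synthetic import (
    SyntheticSpec,
    default_scenarios,
    generate_background,
    generate_known_answer_case,
)


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def background(spec):
    return generate_background(spec)


@pytest.fixture(scope="session")
def scenarios(spec):
    return default_scenarios(spec)


@pytest.fixture(scope="session")
def known_answer():
    return generate_known_answer_case()
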
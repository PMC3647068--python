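import pytest

from pilusim import builtin_table, transition_model


@pytest.fixture(scope="session")
def equal_model():
    return transition_model(builtin_table("equal"))


@pytest.fixture(scope="session")
def in_vitro_model():
    return transition_model(builtin_table("in_vitro"))


@pytest.fixture(scope="session")
def hypothetical_model():
    return transition_model(builtin_table("hypothetical_R"))
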
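import pytest

from coldlife import core_model, synthetic


@pytest.fixture(scope="session")
def params():
    """Model constants calibrated from the default printed anchors."""
    return core_model.default_params()


@pytest.fixture(scope="session")
def low_gsh():
    return synthetic.load_scenario("low_GSH_5C")


@pytest.fixture(scope="session")
def high_gsh():
    return synthetic.load_scenario("high_GSH_5C")


@pytest.fixture(scope="session")
def wildtype_1c():
    return synthetic.load_scenario("wildtype_1C")
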
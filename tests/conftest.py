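import pytest

from leafosc.biochem import MeteoInputs, SpeciesParams, kinetics_at


@pytest.fixture(scope="session")
def params():
    return SpeciesParams()


@pytest.fixture
def moderate_meteo():
    return MeteoInputs(Q=1000.0, Ta=30.0, D=2.0, ca=400.0, P=95.0)


@pytest.fixture
def kin25(params):
    """Kinetics bundle at exactly 25 °C and Q=1000."""
    return kinetics_at(MeteoInputs(Q=1000.0, Ta=25.0, D=1.5, ca=400.0, P=100.0), params)
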
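import pytest
from hypothesis import HealthCheck, settings

from porefep import synthetic
from porefep.thermo import ThermoContext

settings.register_profile(
    "porefep",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("porefep")


@pytest.fixture(scope="session")
def ctx():
    """Default thermodynamic context (300 K)."""
    return ThermoContext()


@pytest.fixture(scope="session")
def pentamer():
    """C5-symmetric Calpha-only pentamer with hand-computable geometry."""
    return synthetic.gen_pentamer_structure()
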
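import pytest
from hypothesis import HealthCheck, settings

from capab.assay_sim import default_params, panel_conditions, simulate_timecourse
from capab.energetics import EnergeticsModel
from capab.speciation import MicroPKSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pks():
    return MicroPKSet()


@pytest.fixture(scope="session")
def model():
    return EnergeticsModel()


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def entry1_noiseless(params):
    """Noiseless simulation of the standard assay: 2 mM Cap, 2 mM ATP, 50 mM HCO3."""
    return simulate_timecourse(panel_conditions()[0], params)


@pytest.fixture(scope="session")
def noiseless_panel(params):
    return [simulate_timecourse(c, params) for c in panel_conditions()]
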
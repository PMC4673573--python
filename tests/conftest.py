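import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")

from mlgkit.digestion_sim import RULE_SETS
from mlgkit.glucan_core import parse_chain
from mlgkit.synthetic_data import SpectrumSimConfig, make_reference_fixtures


@pytest.fixture(scope="session")
def gh12():
    return RULE_SETS["GH12_aniger"]


@pytest.fixture(scope="session")
def gh16():
    return RULE_SETS["GH16_trichoderma"]


@pytest.fixture(scope="session")
def gh17():
    return RULE_SETS["GH17_barley"]


@pytest.fixture(scope="session")
def c5b():
    """The mixed-linkage pentasaccharide carrying a cellobiosyl unit."""
    return parse_chain("G3G4G3G4G")


@pytest.fixture(scope="session")
def cellopentaose():
    return parse_chain("G4G4G4G4G")


@pytest.fixture(scope="session")
def laminaripentaose():
    return parse_chain("G3G3G3G3G")


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free spectrum simulation (exact theoretical m/z)."""
    return SpectrumSimConfig(mz_sigma=0.0, n_noise_peaks=0, seed=7)


@pytest.fixture(scope="session")
def reference_spectra():
    return make_reference_fixtures()
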
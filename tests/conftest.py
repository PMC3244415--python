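import pytest

from vulnmeta import VulnerabilityModel, estimate_from_ci, simulate_collection
from vulnmeta.simulate import CollectionConfig


@pytest.fixture(scope="session")
def model():
    return VulnerabilityModel()


@pytest.fixture(scope="session")
def null_model():
    """Interaction switched off: carrier and non-carrier risks coincide."""
    return VulnerabilityModel(beta_GL=0.0)


@pytest.fixture(scope="session")
def collection(model):
    """One seeded default-size collection shared across tests."""
    return simulate_collection(model, CollectionConfig(), seed=20240601)


@pytest.fixture(scope="session")
def printed_strata():
    """Carrier / non-carrier per-mmol/L statin effects as printed (2 dp)."""
    carriers = estimate_from_ci(0.73, 0.66, 0.80)
    non_carriers = estimate_from_ci(0.83, 0.76, 0.91)
    return carriers, non_carriers
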
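import pytest
from hypothesis import HealthCheck, settings

from pvdkit import VariantPeptide, default_registry, pao1_scaffold
from pvdkit.mass_core import BuildingBlock, Registry, Scaffold

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def scaffold():
    return pao1_scaffold()


@pytest.fixture(scope="session")
def native(scaffold):
    return VariantPeptide(scaffold)


@pytest.fixture(scope="session")
def toy_registry(registry):
    """Default registry plus a round-number chromophore for linear-toy oracles."""
    blocks = list(registry)
    blocks.append(BuildingBlock("ChrToy", "toy chromophore", "chromophore_acyl", 100.0))
    return Registry(blocks)


@pytest.fixture(scope="session")
def linear_toy_scaffold():
    """Eight glycines on a 100-Da chromophore, no macrocycle."""
    return Scaffold(("Gly",) * 8, "ChrToy", "succinamide", cycle_span=None)
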
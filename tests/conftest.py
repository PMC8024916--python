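import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eraptype import catalog as catalog_mod
from eraptype.popgen import PhasedPanel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cat():
    return catalog_mod.load_catalog()


@pytest.fixture(scope="session")
def erap1_sites():
    return catalog_mod.erap1_sites()


@pytest.fixture
def toy_panel(cat):
    """Ten samples with known allotype composition (hand-countable)."""
    hap = cat.haplotype
    pairs = [
        (hap("2"), hap("8")),
        (hap("2"), hap("2")),
        (hap("8"), hap("2")),
        (hap("1"), hap("10")),
        (hap("3"), hap("3")),
        (hap("2"), hap("5")),
        (hap("8"), hap("8")),
        (hap("10"), hap("10")),
        (hap("6"), hap("7")),
        ("EPIGMKDRE", hap("2")),  # one unassigned chromosome
    ]
    return PhasedPanel(
        samples=[f"S{i}" for i in range(10)],
        populations=["EUR"] * 5 + ["AFR"] * 5,
        hap1=[a for a, _ in pairs],
        hap2=[b for _, b in pairs],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
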
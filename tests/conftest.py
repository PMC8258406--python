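import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pstpcr import primer_design, synth  # noqa: E402


@pytest.fixture(scope="session")
def pst_catalog():
    return primer_design.load_primer_catalog("pst")


@pytest.fixture(scope="session")
def ssp_catalog():
    return primer_design.load_primer_catalog("ssp")


@pytest.fixture(scope="session")
def pst_primers():
    return primer_design.load_pst_primers()


@pytest.fixture(scope="session")
def ssp_primers():
    return primer_design.load_ssp_primers()


@pytest.fixture(scope="session")
def tail_primer():
    return primer_design.load_tail_primer()


@pytest.fixture(scope="session")
def cohort():
    """One deterministic parents-and-hybrids cohort shared across tests."""
    return synth.make_cohort(seed=11)
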
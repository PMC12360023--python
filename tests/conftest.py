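import pytest
from hypothesis import HealthCheck, settings

from ccinfer.elements import default_element_table
from ccinfer.fixtures import reference_molecule, reference_fringe
from ccinfer.twolayer import decompose

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table():
    return default_element_table()


@pytest.fixture(scope="session")
def isomers():
    return {name: reference_molecule(name)
            for name in ("catechol", "resorcinol", "hydroquinone")}


@pytest.fixture(scope="session")
def benzene():
    return reference_molecule("benzene")


@pytest.fixture(scope="session")
def psi1():
    return reference_fringe("psi1")


@pytest.fixture(scope="session")
def psi2():
    return reference_fringe("psi2")


@pytest.fixture(scope="session")
def resorcinol_decomp(isomers):
    return decompose(isomers["resorcinol"])
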
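import pytest

from heliamp.design import PeptideFormula, enumerate_family, wheel_angles
from heliamp.fileio import load_packaged_mhc, load_packaged_mic_table
from heliamp.physchem import load_scale


@pytest.fixture(scope="session")
def formula():
    return PeptideFormula()


@pytest.fixture(scope="session")
def geometry():
    return wheel_angles(11)


@pytest.fixture(scope="session")
def family(formula, geometry):
    return enumerate_family(formula, geometry)


@pytest.fixture(scope="session")
def eisenberg():
    return load_scale("eisenberg-consensus")


@pytest.fixture(scope="session")
def mic_table():
    return load_packaged_mic_table()


@pytest.fixture(scope="session")
def mhc_panel():
    return load_packaged_mhc()
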
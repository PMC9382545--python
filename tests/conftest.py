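import pytest

from clinrules import build_facts, fixtures


@pytest.fixture(scope="session")
def kb():
    return fixtures.reference_kb()


@pytest.fixture(scope="session")
def patient0():
    return fixtures.patient_zero()


@pytest.fixture(scope="session")
def facts0(kb, patient0):
    return build_facts(patient0, kb)
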
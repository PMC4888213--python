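import pytest

from oncointerp.knowledgebase import packaged_kb
from oncointerp.synthetic import table_fixtures


@pytest.fixture(scope="session")
def kb():
    return packaged_kb()


@pytest.fixture(scope="session")
def fixtures(kb):
    return table_fixtures(kb)


@pytest.fixture(scope="session")
def colorectal(fixtures):
    return fixtures["colorectal"]


@pytest.fixture(scope="session")
def mtc(fixtures):
    return fixtures["mtc"]


@pytest.fixture(scope="session")
def breast(fixtures):
    return fixtures["breast"]


@pytest.fixture(scope="session")
def p0015(fixtures):
    return fixtures["p0015"][0]


@pytest.fixture(scope="session")
def by_patient(fixtures):
    return {p.patient_id: p for group in fixtures.values() for p in group}
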
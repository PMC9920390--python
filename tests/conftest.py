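import pytest
from rdkit import RDLogger

from casepy.fixtures import FixtureSpec, make_fixture_kb
from casepy.knowledge_base import accumulate_statistics, build_hose_library

RDLogger.DisableLog("rdApp.warning")


@pytest.fixture(scope="session")
def fixture_kb():
    return make_fixture_kb(FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def hose_library(fixture_kb):
    return build_hose_library(fixture_kb, max_sphere=6)


@pytest.fixture(scope="session")
def kb_stats(fixture_kb):
    return accumulate_statistics(fixture_kb)
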
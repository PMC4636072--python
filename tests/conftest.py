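import sqlite3

import pytest

from armdb import ArmStore, NodePathStore, build_fixture_suite, map_schema


@pytest.fixture(scope="session")
def suite():
    return build_fixture_suite()


@pytest.fixture(scope="session")
def suite_map(suite):
    return suite.by_id


@pytest.fixture(scope="session")
def schema(suite):
    return map_schema(suite.archetypes, suite.templates, suite.eav_mappings)


@pytest.fixture
def arm_store(schema, suite_map):
    conn = sqlite3.connect(":memory:")
    yield ArmStore.deploy(schema, suite_map, conn)
    conn.close()


@pytest.fixture
def np_store(schema, suite_map):
    conn = sqlite3.connect(":memory:")
    yield NodePathStore.deploy(schema, suite_map, conn)
    conn.close()
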
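"""Archetype version handling: shared tables, per-version tables, migration."""

import sqlite3

import pytest

from armdb import ArchetypeInstance, ArmStore, map_schema
from armdb.archetype import parse_archetype
from armdb.ddl import apply_migration, emit_revision_alter
from armdb.errors import MigrationError
from armdb.mapper import (
    MERGE_AND_CONVERT,
    TABLE_PER_VERSION,
    ConversionSpec,
    merge_versions,
)
from armdb.template import parse_template

V1 = """
archetype_id: openEHR-EHR-OBSERVATION.vitals.v1
nodes:
  - {name: id, kind: basic, type: DvIdentifier, occurrence: 1..1, text: {en: Id}}
  - {name: heartRate, kind: basic, type: DvCount, occurrence: 1..1, text: {en: Heart rate}}
"""
REVISED = V1 + \
    "  - {name: note, kind: basic, type: DvText, occurrence: 0..1, text: {en: Note}}\n"
V2 = """
archetype_id: openEHR-EHR-OBSERVATION.vitals.v2
nodes:
  - {name: id, kind: basic, type: DvIdentifier, occurrence: 1..1, text: {en: Id}}
  - {name: heartRate, kind: basic, type: DvQuantity, occurrence: 0..1, text: {en: Heart rate}}
"""
TMPL = ("template_id: vitals.oet\narchetype_id: openEHR-EHR-OBSERVATION.vitals.v1\n"
        "arm: {identification_item: id}\n")


@pytest.fixture
def deployed():
    v1 = parse_archetype(V1)
    schema = map_schema([v1], [parse_template(TMPL)])
    conn = sqlite3.connect(":memory:")
    store = ArmStore.deploy(schema, {v1.id_text: v1}, conn)
    for i in range(6):
        store.store_instance(ArchetypeInstance(
            v1.id_text, {"id": {"id": f"V{i}"}, "heartRate": {"magnitude": 60 + i}}))
    return v1, schema, conn, store


def test_revision_shares_the_table_with_data_intact(deployed):
    v1, schema, conn, store = deployed
    rev = parse_archetype(REVISED)
    table = schema.table_for(v1.id_text)
    before = {c.name for c in table.columns}
    schema, plan = merge_versions(schema, v1, rev)
    assert plan is None
    assert schema.archetype_tables[rev.id_text] == schema.archetype_tables[v1.id_text]
    added = [c for c in table.columns if c.name not in before]
    assert [(c.name, c.nullable) for c in added] == [("note_value", True)]
    conn.executescript(emit_revision_alter(table, added))
    assert store.count(table.name) == 6  # old rows survive
    suite = {v1.id_text: v1, rev.id_text: rev}
    store2 = ArmStore(schema, suite, conn)
    store2.store_instance(ArchetypeInstance(
        rev.id_text, {"id": {"id": "V9"}, "heartRate": {"magnitude": 80},
                      "note": {"value": "post-revision"}}))
    back = store2.retrieve_instance(rev.id_text, "V9")
    assert back.values["note"] == {"value": "post-revision"}
    # pre-revision rows read back through the revised archetype, note absent
    old = store2.retrieve_instance(rev.id_text, "V0")
    assert old.values["heartRate"] == {"magnitude": 60} and "note" not in old.values


def test_new_version_table_per_version_keeps_the_version_suffix(deployed):
    v1, schema, conn, _store = deployed
    v2 = parse_archetype(V2)
    schema, plan = merge_versions(schema, v1, v2, TABLE_PER_VERSION)
    assert plan is None
    assert schema.archetype_tables[v2.id_text] == "OVitalsV2"
    assert schema.archetype_tables[v1.id_text] == "OVitals"


def test_specialization_always_gets_its_own_table(deployed):
    v1, schema, conn, _store = deployed
    sub = parse_archetype(V1.replace(
        "openEHR-EHR-OBSERVATION.vitals.v1", "openEHR-EHR-OBSERVATION.vitals-icu.v1"
    ) + "parent_id: openEHR-EHR-OBSERVATION.vitals.v1\n")
    schema, plan = merge_versions(schema, v1, sub)
    assert plan is None
    assert schema.archetype_tables[sub.id_text] == "OVitalsIcu"
    assert schema.archetype_tables[sub.id_text] != schema.archetype_tables[v1.id_text]


def test_merge_and_convert_requires_a_conversion_spec(deployed):
    v1, schema, _conn, _store = deployed
    v2 = parse_archetype(V2)
    with pytest.raises(MigrationError, match="conversion"):
        merge_versions(schema, v1, v2, MERGE_AND_CONVERT)


def test_merge_and_convert_migrates_with_checksums(deployed):
    v1, schema, conn, _store = deployed
    v2 = parse_archetype(V2)
    source_vals = dict(conn.execute("SELECT id, heartRate_magnitude FROM OVitals"))
    conv = ConversionSpec(mappings=[
        ("id", "id", "identity"),
        ("heartRate_magnitude", "heartRate_magnitude", "float"),
    ])
    schema, plan = merge_versions(schema, v1, v2, MERGE_AND_CONVERT, conv)
    report = apply_migration(plan, conn)
    assert report["ok"] and report["rows"] == 6
    target_vals = dict(conn.execute("SELECT id, heartRate_magnitude FROM OVitals"))
    # per-column multiset preservation (the float transform keeps the values)
    assert sorted(target_vals) == sorted(source_vals)
    assert sorted(float(v) for v in target_vals.values()) == \
        sorted(float(v) for v in source_vals.values())
    # the old table is gone; the new definition owns the name
    assert schema.table_for(v2.id_text).name == "OVitals"
    assert conn.execute(
        "SELECT COUNT(*) FROM sqlite_master WHERE name LIKE '%migration%'"
    ).fetchone()[0] == 0


def test_migration_aborts_before_copy_without_notnull_mapping(deployed):
    v1, schema, conn, _store = deployed
    # v2 keeps heartRate mandatory: its magnitude column is NOT NULL and the
    # conversion below forgets it
    v2 = parse_archetype(V2.replace("occurrence: 0..1", "occurrence: 1..1"))
    conv = ConversionSpec(mappings=[("id", "id", "identity")])
    schema, plan = merge_versions(schema, v1, v2, MERGE_AND_CONVERT, conv)
    with pytest.raises(MigrationError, match="aborting before copy"):
        apply_migration(plan, conn)
    # source untouched by the pre-flight abort
    assert conn.execute("SELECT COUNT(*) FROM OVitals").fetchone()[0] == 6


def test_migration_over_empty_source_succeeds():
    v1 = parse_archetype(V1)
    schema = map_schema([v1], [parse_template(TMPL)])
    conn = sqlite3.connect(":memory:")
    ArmStore.deploy(schema, {v1.id_text: v1}, conn)
    v2 = parse_archetype(V2)
    conv = ConversionSpec(mappings=[
        ("id", "id", "identity"),
        ("heartRate_magnitude", "heartRate_magnitude", "float"),
    ])
    schema, plan = merge_versions(schema, v1, v2, MERGE_AND_CONVERT, conv)
    report = apply_migration(plan, conn)
    assert report["ok"] and report["rows"] == 0
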
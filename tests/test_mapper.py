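"""Schema mapping: the eight rules, naming, embedding, propagation."""

import numpy as np
import pytest

from armdb.archetype import parse_archetype
from armdb.errors import MappingError, SlotCycleError
from armdb.mapper import (
    ARCHETYPE_MAIN,
    FOREIGN_KEY,
    GENERATED_ID,
    PROPAGATED_QUERY,
    MapperConfig,
    make_names,
    map_schema,
    shorten,
)
from armdb.template import parse_template

GOLDEN_TABLES = {
    "DPersonPatient", "IRequestImagingExam", "OImagingExam",
    "OImagingExamImageDetails", "IRequestLabTest", "OLabTestGeneral",
    "OLabTestGeneralStructureResult", "OLabTestBloodGases",
    "OLabTestFullBloodCount", "OLabTestLiverFunction", "OLabTestThyroid",
    "OLabTestUreaAndElectrolytes",
}


def test_suite_maps_to_the_twelve_workload_tables(schema):
    assert set(schema.tables) == GOLDEN_TABLES


def test_identification_items_become_unique_clustered_keys(schema):
    t = schema.tables["DPersonPatient"]
    assert t.key_column == "patientIdentifier_identifier_id"
    assert not t.key_generated
    (ci,) = [ix for ix in t.indexes if ix.clustered]
    assert ci.unique and ci.columns == ("patientIdentifier_identifier_id",)


def test_archetype_without_identification_item_gets_generated_key(schema):
    """Panels carry no template: rule 3 adds an invisible generated id
    carrying the unique clustered index."""
    t = schema.tables["OLabTestBloodGases"]
    assert t.key_generated and t.key_column == "id"
    col = t.column("id")
    assert col.role == GENERATED_ID and col.provenance == ("generated",)
    # invisible: no archetype path resolves to the generated column
    assert all(v != (t.name, "id") for v in schema.provenance.values())


def test_minimal_archetype_single_optional_text():
    arch = parse_archetype(
        "archetype_id: openEHR-EHR-OBSERVATION.mini.v1\nnodes:\n"
        "  - {name: item, kind: basic, type: DvText, occurrence: 0..1, text: {en: Item}}\n"
    )
    t = parse_template(
        "template_id: mini.oet\narchetype_id: openEHR-EHR-OBSERVATION.mini.v1\narm: {}\n"
    )
    schema = map_schema([arch], [t])
    (table,) = schema.tables.values()
    assert [(c.name, c.storage_kind, c.role) for c in table.columns] == [
        ("id", "INTEGER", GENERATED_ID), ("item_value", "NVARCHAR", "DATA"),
    ]


def test_single_occurrence_slots_embed_target_items(schema):
    """Patient demographics: name/details cluster items appear inline in
    the person table, pathed under the slot."""
    t = schema.tables["DPersonPatient"]
    names = {c.name for c in t.columns}
    assert {"personName_name_value", "personDetails_sex_definingCode_code",
            "personDetails_birthDate_value"} <= names
    prov = schema.resolve("openEHR-DEMOGRAPHIC-PERSON.person-patient.v1",
                          "personName/name", "value")
    assert prov == ("DPersonPatient", "personName_name_value")


def test_many_slot_becomes_foreign_key_in_target_table(schema):
    t = schema.tables["OImagingExam"]
    fk = t.column("IRequestImagingExam_id")
    assert fk.role == FOREIGN_KEY
    assert any(f.column == "IRequestImagingExam_id" and
               f.target_table == "IRequestImagingExam" and f.target_column == "id"
               for f in t.foreign_keys)


def test_query_items_propagate_with_suppression(schema):
    """Rule 7 copies the request's query items into the exam table; the
    template suppresses two of the three."""
    t = schema.tables["OImagingExam"]
    names = {c.name for c in t.columns}
    assert "IRequestImagingExam_patient_value" in names
    assert "IRequestImagingExam_requestorIdentifier_value" not in names
    assert "IRequestImagingExam_receiverIdentifier_value" not in names
    col = t.column("IRequestImagingExam_patient_value")
    assert col.role == PROPAGATED_QUERY
    assert "IRequestImagingExam_patient_value" in t.indexed_columns(clustered=False)


def test_result_child_table_carries_propagated_indexed_patient(schema):
    t = schema.tables["OLabTestGeneralStructureResult"]
    col = t.column("OLabTestGeneral_patient_value")
    assert col.role == PROPAGATED_QUERY
    assert "OLabTestGeneral_patient_value" in t.indexed_columns(clustered=False)
    assert t.parent_table == "OLabTestGeneral" and t.fk_column == "OLabTestGeneral_id"


def test_every_table_has_one_unique_clustered_index_on_its_key(schema):
    for t in schema.tables.values():
        clustered = [ix for ix in t.indexes if ix.clustered]
        assert len(clustered) == 1 and clustered[0].unique, t.name
        assert clustered[0].columns == (t.key_column,), t.name


def test_foreign_key_graph_is_acyclic_over_main_tables(schema):
    edges = {}
    for t in schema.tables.values():
        if t.origin != ARCHETYPE_MAIN:
            continue
        for fk in t.foreign_keys:
            if schema.tables[fk.target_table].origin == ARCHETYPE_MAIN:
                edges.setdefault(t.name, set()).add(fk.target_table)

    seen, stack = set(), set()

    def visit(n):
        assert n not in stack, f"cycle through {n}"
        if n in seen:
            return
        stack.add(n)
        for m in edges.get(n, ()):
            visit(m)
        stack.discard(n)
        seen.add(n)

    for n in list(edges):
        visit(n)


def test_provenance_is_a_bijection_over_data_columns(schema):
    forward = {}
    for key, (tname, col) in schema.provenance.items():
        assert (tname, col) not in forward, (tname, col)
        forward[(tname, col)] = key
    for t in schema.tables.values():
        for c in t.columns:
            if c.role == "DATA":
                assert (t.name, c.name) in forward, (t.name, c.name)
            else:
                assert (t.name, c.name) not in forward


def test_embedding_cycle_detection():
    a = parse_archetype(
        "archetype_id: openEHR-EHR-CLUSTER.alpha.v1\nnodes:\n"
        "  - {name: toB, kind: slot, target: openEHR-EHR-CLUSTER.beta.v1, "
        "occurrence: 0..1, text: {en: To B}}\n"
    )
    b = parse_archetype(
        "archetype_id: openEHR-EHR-CLUSTER.beta.v1\nnodes:\n"
        "  - {name: toA, kind: slot, target: openEHR-EHR-CLUSTER.alpha.v1, "
        "occurrence: 0..1, text: {en: To A}}\n"
    )
    t = parse_template(
        "template_id: a.oet\narchetype_id: openEHR-EHR-CLUSTER.alpha.v1\narm: {}\n"
    )
    with pytest.raises(SlotCycleError):
        map_schema([a, b], [t])


def test_one_slot_and_many_slot_forms_cover_the_same_leaves():
    """Embedding (upper 1) and foreign-key linking (upper *) are two shapes
    over identical leaf fields."""
    target = (
        "archetype_id: openEHR-EHR-CLUSTER.part.v1\nnodes:\n"
        "  - {name: a, kind: basic, type: DvText, occurrence: 0..1, text: {en: A}}\n"
        "  - {name: b, kind: basic, type: DvQuantity, occurrence: 0..1, text: {en: B}}\n"
    )
    host = (
        "archetype_id: openEHR-EHR-OBSERVATION.host.v1\nnodes:\n"
        "  - {name: id, kind: basic, type: DvIdentifier, occurrence: 1..1, text: {en: Id}}\n"
        "  - {name: part, kind: slot, target: openEHR-EHR-CLUSTER.part.v1, "
        "occurrence: 0..UPPER, text: {en: Part}}\n"
    )
    tmpl = ("template_id: h.oet\narchetype_id: openEHR-EHR-OBSERVATION.host.v1\n"
            "arm: {identification_item: id}\n")
    part_tmpl = ("template_id: p.oet\narchetype_id: openEHR-EHR-CLUSTER.part.v1\narm: {}\n")

    one = map_schema([parse_archetype(host.replace("UPPER", "1")), parse_archetype(target)],
                     [parse_template(tmpl)])
    many = map_schema([parse_archetype(host.replace("UPPER", "*")), parse_archetype(target)],
                      [parse_template(tmpl), parse_template(part_tmpl)])

    embedded = {(p.split("/", 1)[1], s) for (aid, p, s) in one.provenance
                if aid.endswith("host.v1") and p.startswith("[part]/")}
    standalone = {(p, s) for (aid, p, s) in many.provenance
                  if aid.endswith("part.v1")}
    assert embedded == standalone and embedded


def test_table_and_column_naming_rules(suite):
    general = suite.archetype("openEHR-EHR-OBSERVATION.lab_test-general.v1")
    person = suite.archetype("openEHR-DEMOGRAPHIC-PERSON.person-patient.v1")
    assert make_names(general) == "OLabTestGeneral"
    assert make_names(general, "structureResult") == "OLabTestGeneralStructureResult"
    assert make_names(person, "patientIdentifier/identifier", "id") == \
        "patientIdentifier_identifier_id"
    # a trailing name segment equal to the field suffix is not repeated
    assert make_names(general, "id", "id") == "id"


def test_long_names_shorten_deterministically_and_stay_unique():
    long_name = "X" * 300
    s = shorten(long_name, 64)
    assert len(s) == 64 and s == shorten(long_name, 64)

    rng = np.random.default_rng(42)
    seen = set()
    alphabet = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    for _ in range(100_000):
        name = "".join(rng.choice(alphabet, size=80))
        seen.add(shorten(name, 30))
    assert len(seen) == 100_000  # no collisions across distinct long names


def test_identical_full_names_collide_loudly():
    a = parse_archetype(
        "archetype_id: openEHR-EHR-OBSERVATION.twin.v1\nnodes:\n"
        "  - {name: id, kind: basic, type: DvIdentifier, occurrence: 1..1, text: {en: Id}}\n"
    )
    b = parse_archetype(
        "archetype_id: openEHR-EHR-OBSERVATION.twin.v2\nnodes:\n"
        "  - {name: id, kind: basic, type: DvIdentifier, occurrence: 1..1, text: {en: Id}}\n"
    )
    ta = parse_template("template_id: a.oet\narchetype_id: openEHR-EHR-OBSERVATION.twin.v1\n"
                        "arm: {identification_item: id}\n")
    tb = parse_template("template_id: b.oet\narchetype_id: openEHR-EHR-OBSERVATION.twin.v2\n"
                        "arm: {identification_item: id}\n")
    with pytest.raises(MappingError, match="collision"):
        map_schema([a, b], [ta, tb])  # both versions strip to "OTwin"


def test_one_template_per_archetype_enforced(suite):
    t1 = suite.template_for("openEHR-EHR-OBSERVATION.imaging_exam.v1")
    with pytest.raises(MappingError, match="one template per archetype"):
        map_schema(suite.archetypes, list(suite.templates) + [t1], suite.eav_mappings)


def test_unresolved_slot_target_is_an_error():
    host = parse_archetype(
        "archetype_id: openEHR-EHR-OBSERVATION.host.v1\nnodes:\n"
        "  - {name: part, kind: slot, target: openEHR-EHR-CLUSTER.gone.v1, "
        "occurrence: 0..1, text: {en: Part}}\n"
    )
    t = parse_template("template_id: h.oet\narchetype_id: openEHR-EHR-OBSERVATION.host.v1\n"
                       "arm: {}\n")
    with pytest.raises(MappingError, match="unresolved"):
        map_schema([host], [t])


def test_path_column_mode_uses_full_paths(suite):
    config = MapperConfig(column_mode="path")
    schema = map_schema(suite.archetypes, suite.templates, suite.eav_mappings,
                        config=config)
    t = schema.tables["OLabTestBloodGases"]
    assert t.has_column("[paO2]_magnitude")
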
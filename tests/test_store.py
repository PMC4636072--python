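"""ARM instance persistence and query execution."""

import itertools

import numpy as np
import pytest

from armdb import ArchetypeInstance
from armdb.errors import (
    DuplicateKeyError,
    NotFoundError,
    QueryError,
    ValidationError,
)
from armdb.fixtures import GENERALIZED_LAB, REQUEST_IMAGING
from armdb.instance import instances_equal, random_instance, validate_instance
from armdb.query import SUBJECT, Condition, query
from armdb.store import load_instances


def _general(key="LAB1", patient="P1", reps=3):
    return ArchetypeInstance(GENERALIZED_LAB, {
        "id": {"id": key},
        "receiverOrderIdentifier": {"value": f"LRQ-{key}"},
        "patient": {"value": patient},
        "structureResult": [
            {"testItem": {"value": f"Item {i}"},
             "result": {"value": str(10 * (i + 1))},
             "resultUnit": {"value": "mmol/L"}}
            for i in range(reps)
        ],
    })


def test_multi_occurrence_repetitions_become_child_rows(arm_store):
    """One main row plus one child row per repetition, each carrying the
    foreign key and the propagated patient value."""
    arm_store.store_instance(_general())
    assert arm_store.count("OLabTestGeneral") == 1
    rows = arm_store.conn.execute(
        "SELECT OLabTestGeneral_id, ordinal, testItem_value, "
        "OLabTestGeneral_patient_value FROM OLabTestGeneralStructureResult "
        "ORDER BY ordinal"
    ).fetchall()
    assert rows == [
        ("LAB1", 0, "Item 0", "P1"),
        ("LAB1", 1, "Item 1", "P1"),
        ("LAB1", 2, "Item 2", "P1"),
    ]


def test_single_occurrence_item_rejects_repetitions(arm_store):
    inst = _general()
    inst.values["patient"] = [{"value": "P1"}, {"value": "P2"}]
    with pytest.raises(ValidationError, match="single-occurrence"):
        arm_store.store_instance(inst)


def test_missing_mandatory_leaf_rejected(arm_store, suite_map):
    inst = _general()
    del inst.values["patient"]
    with pytest.raises(ValidationError, match="mandatory"):
        validate_instance(inst, suite_map)


def test_duplicate_identification_value_raises_unique_violation(arm_store):
    arm_store.store_instance(_general("LAB7"))
    with pytest.raises(DuplicateKeyError):
        arm_store.store_instance(_general("LAB7"))


def test_retrieve_unknown_key_is_not_found(arm_store):
    with pytest.raises(NotFoundError):
        arm_store.retrieve_instance(GENERALIZED_LAB, "nope")


def test_empty_repetition_list_roundtrips_to_empty_list(arm_store, suite_map):
    inst = _general(reps=0)
    key = arm_store.store_instance(inst)
    back = arm_store.retrieve_instance(GENERALIZED_LAB, key)
    assert back.values["structureResult"] == []
    assert instances_equal(inst, back, suite_map)


def test_randomized_roundtrip_over_all_tabled_archetypes(arm_store, suite, schema,
                                                         suite_map):
    """retrieve(store(x)) is x, structurally, for conformant random
    instances of every archetype with a table."""
    rng = np.random.default_rng(11)
    keys = (f"K{i:06d}" for i in itertools.count())
    tabled = [a for a in suite.archetypes if a.id_text in schema.archetype_tables]
    for i in range(120):
        arch = tabled[i % len(tabled)]
        inst = random_instance(arch, suite_map, rng, keys)
        key = arm_store.store_instance(inst)
        back = arm_store.retrieve_instance(arch.id_text, key)
        assert instances_equal(inst, back, suite_map), arch.id_text


def test_slot_children_store_into_their_own_table(arm_store):
    inst = ArchetypeInstance(REQUEST_IMAGING, {
        "id": {"id": "IRQ1"}, "patient": {"value": "P1"},
        "receiverIdentifier": {"value": "RIS1"},
        "examItems": [
            {"archetype_id": "openEHR-EHR-OBSERVATION.imaging_exam.v1",
             "values": {"id": {"id": "IEX1"}, "patient": {"value": "P1"},
                        "imageDetails": [{"imageNumber": {"magnitude": 1}}]}},
        ],
    })
    arm_store.store_instance(inst)
    fk, prop = arm_store.conn.execute(
        "SELECT IRequestImagingExam_id, IRequestImagingExam_patient_value "
        "FROM OImagingExam WHERE id='IEX1'").fetchone()
    assert (fk, prop) == ("IRQ1", "P1")
    back = arm_store.retrieve_instance(REQUEST_IMAGING, "IRQ1")
    assert back.values["examItems"][0]["values"]["id"] == {"id": "IEX1"}


def test_vacuous_conjunction_selects_every_instance(arm_store):
    for i in range(4):
        arm_store.store_instance(_general(f"L{i}", patient=f"P{i%2}"))
    rs = arm_store.run_query(query(GENERALIZED_LAB))
    assert rs.rows == ["L0", "L1", "L2", "L3"]


def test_subject_grouping_deduplicates_patients(arm_store):
    for i in range(4):
        arm_store.store_instance(_general(f"L{i}", patient=f"P{i%2}"))
    rs = arm_store.run_query(query(GENERALIZED_LAB, group_unit=SUBJECT))
    assert rs.rows == ["P0", "P1"]


def test_repetition_conditions_default_to_independent_exists(arm_store):
    """Unlabeled conditions on one group may match different repetitions of
    the same instance; labeled conditions must hit the same repetition."""
    arm_store.store_instance(_general("L1"))  # items: (Item 0,10) (Item 1,20) (Item 2,30)
    independent = query(GENERALIZED_LAB, [
        Condition("structureResult/testItem", "value", "=", "Item 0"),
        Condition("structureResult/result", "value", ">=", 25),
    ])
    assert arm_store.run_query(independent).rows == ["L1"]
    bound = query(GENERALIZED_LAB, [
        Condition("structureResult/testItem", "value", "=", "Item 0", group="g"),
        Condition("structureResult/result", "value", ">=", 25, group="g"),
    ])
    assert arm_store.run_query(bound).rows == []
    bound_ok = query(GENERALIZED_LAB, [
        Condition("structureResult/testItem", "value", "=", "Item 2", group="g"),
        Condition("structureResult/result", "value", ">=", 25, group="g"),
    ])
    assert arm_store.run_query(bound_ok).rows == ["L1"]


def test_numeric_comparison_on_text_storage_casts(arm_store):
    arm_store.store_instance(_general("L1"))
    rs = arm_store.run_query(query(GENERALIZED_LAB, [
        Condition("structureResult/result", "value", ">=", 30)]))
    assert rs.rows == ["L1"]
    rs = arm_store.run_query(query(GENERALIZED_LAB, [
        Condition("structureResult/result", "value", ">=", 31)]))
    assert rs.rows == []


def test_like_comparator(arm_store):
    arm_store.store_instance(_general("L1", patient="P-alpha"))
    arm_store.store_instance(_general("L2", patient="Q-beta"))
    rs = arm_store.run_query(query(GENERALIZED_LAB, [
        Condition("patient", "value", "LIKE", "P-%")]))
    assert rs.rows == ["L1"]


def test_unresolvable_path_raises(arm_store):
    arm_store.store_instance(_general("L1"))
    with pytest.raises((QueryError, Exception)):
        arm_store.run_query(query(GENERALIZED_LAB, [
            Condition("noSuchItem", "value", "=", 1)]))


def test_join_strategy_agrees_with_stepwise(arm_store):
    for i in range(6):
        arm_store.store_instance(_general(f"L{i}", patient=f"P{i%3}", reps=i))
    specs = [
        query(GENERALIZED_LAB, [Condition("patient", "value", "=", "P1")]),
        query(GENERALIZED_LAB, [
            Condition("structureResult/result", "value", ">=", 20),
            Condition("patient", "value", "LIKE", "P%"),
        ]),
        query(GENERALIZED_LAB, [
            Condition("structureResult/testItem", "value", "=", "Item 1", group="g"),
            Condition("structureResult/result", "value", "<=", 20, group="g"),
        ]),
    ]
    for spec in specs:
        assert arm_store.run_query(spec, strategy="stepwise").digest() == \
            arm_store.run_query(spec, strategy="join").digest()


def test_propagated_values_equal_parent_values(arm_store, schema):
    """Full-scan consistency: every child row's propagated columns mirror
    its parent row."""
    for i in range(5):
        arm_store.store_instance(_general(f"L{i}", patient=f"P{i}", reps=2))
    rows = arm_store.conn.execute(
        "SELECT c.OLabTestGeneral_patient_value, p.patient_value "
        "FROM OLabTestGeneralStructureResult c "
        "JOIN OLabTestGeneral p ON p.id = c.OLabTestGeneral_id"
    ).fetchall()
    assert rows and all(a == b for a, b in rows)


def test_bulk_load_returns_keys_in_order(arm_store):
    keys = load_instances(arm_store, [_general(f"L{i}") for i in range(3)])
    assert keys == ["L0", "L1", "L2"]
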
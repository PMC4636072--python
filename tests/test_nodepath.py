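"""Node+Path backend: row layout, round-trips, cross-backend equivalence."""

import itertools

import numpy as np
import pytest

from armdb import ArchetypeInstance, InMemoryOracle
from armdb.errors import DuplicateKeyError, NotFoundError
from armdb.fixtures import GENERALIZED_LAB, PANEL_ARCHETYPES
from armdb.instance import instances_equal, random_instance
from armdb.query import Condition, SUBJECT, query
from armdb.synth import DatasetParams, generate_dataset


def _value_rows(store, table):
    return store.conn.execute(
        f"SELECT instance_key, ordinal, node_path, value FROM {table} "
        "WHERE node_path NOT LIKE '~%' AND node_path NOT LIKE '%/~rep' "
        "ORDER BY node_path, ordinal"
    ).fetchall()


def test_one_row_per_populated_leaf_field(np_store):
    bg = PANEL_ARCHETYPES["blood_gases"]
    inst = ArchetypeInstance(bg, {
        "patient": {"value": "P1"},
        "paO2": {"magnitude": 100.0, "units": "mmHg"},
    })
    np_store.store_instance(inst)
    rows = _value_rows(np_store, "OLabTestBloodGases")
    assert len(rows) == 3  # patient + paO2 magnitude + paO2 units
    paths = {r[2] for r in rows}
    assert paths == {"[patient]/value/value", "[paO2]/value/magnitude",
                     "[paO2]/value/units"}


def test_empty_instance_leaves_only_a_registration_row(np_store):
    bg = PANEL_ARCHETYPES["blood_gases"]
    # patient is mandatory; everything else absent
    np_store.store_instance(ArchetypeInstance(bg, {"patient": {"value": "P1"}}))
    all_rows = np_store.conn.execute(
        "SELECT node_path FROM OLabTestBloodGases").fetchall()
    # one registration row plus the single mandatory leaf
    assert sorted(p for (p,) in all_rows) == ["[patient]/value/value", "~key"]


def test_repetitions_write_ordinals(np_store):
    inst = ArchetypeInstance(GENERALIZED_LAB, {
        "id": {"id": "LAB1"}, "patient": {"value": "P1"},
        "structureResult": [
            {"testItem": {"value": f"I{i}"}, "result": {"value": str(i)},
             "resultUnit": {"value": "u"}}
            for i in range(3)
        ],
    })
    np_store.store_instance(inst)
    rows = [r for r in _value_rows(np_store, "OLabTestGeneral")
            if r[2].startswith("[structureResult]")]
    assert len(rows) == 9  # 3 repetitions x 3 fields
    assert sorted({r[1] for r in rows}) == [0, 1, 2]


def test_roundtrip_and_duplicate_and_notfound(np_store, suite, schema, suite_map):
    rng = np.random.default_rng(5)
    keys = (f"N{i:06d}" for i in itertools.count())
    tabled = [a for a in suite.archetypes if a.id_text in schema.archetype_tables]
    for i in range(60):
        arch = tabled[i % len(tabled)]
        inst = random_instance(arch, suite_map, rng, keys)
        key = np_store.store_instance(inst)
        back = np_store.retrieve_instance(arch.id_text, key)
        assert instances_equal(inst, back, suite_map), arch.id_text
    with pytest.raises(NotFoundError):
        np_store.retrieve_instance(GENERALIZED_LAB, "missing")
    inst = ArchetypeInstance(GENERALIZED_LAB, {"id": {"id": "DUP"},
                                               "patient": {"value": "P"}})
    np_store.store_instance(inst)
    with pytest.raises(DuplicateKeyError):
        np_store.store_instance(inst)


def test_empty_table_queries_empty(np_store):
    assert np_store.run_query(query(GENERALIZED_LAB)).rows == []


def test_results_of_one_lab_test_group_under_its_key(np_store):
    """All repetitions of one laboratory test come back under that test's
    instance key."""
    for k in ("LAB1", "LAB2"):
        np_store.store_instance(ArchetypeInstance(GENERALIZED_LAB, {
            "id": {"id": k}, "patient": {"value": "P1"},
            "structureResult": [
                {"testItem": {"value": f"{k}-I{i}"}} for i in range(4)
            ],
        }))
    rs = np_store.run_query(query(GENERALIZED_LAB,
                                  [Condition("id", "id", "=", "LAB2")],
                                  projection="structureResult"))
    assert rs.rows == [("LAB2", 0), ("LAB2", 1), ("LAB2", 2), ("LAB2", 3)]


def test_cross_backend_equivalence_on_a_seeded_dataset(arm_store, np_store,
                                                       schema, suite_map):
    """ARM, Node+Path and the in-memory evaluator return identical result
    sets for retrieval and patient-search query shapes."""
    insts = list(generate_dataset(DatasetParams(seed=9, n_patients=25, scale=0.05)))
    oracle = InMemoryOracle(schema, suite_map)
    for inst in insts:
        arm_store.store_instance(inst, commit=False)
        np_store.store_instance(inst, commit=False)
        oracle.add(inst)
    arm_store.conn.commit()
    np_store.conn.commit()
    bg = PANEL_ARCHETYPES["blood_gases"]
    specs = [
        query(bg, [Condition("paO2", "magnitude", ">=", 129)], group_unit=SUBJECT),
        query(GENERALIZED_LAB, [Condition("patient", "value", "LIKE", "P000%")]),
        query(bg),
    ]
    for spec in specs:
        a = arm_store.run_query(spec)
        n = np_store.run_query(spec)
        o = oracle.run_query(spec)
        assert a.digest() == n.digest() == o.digest()
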
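"""Generalized/specialized translation of queries and instances."""

import sqlite3

import numpy as np
import pytest

from armdb import ArchetypeInstance, ArmStore, load_instances
from armdb.errors import TranslationError
from armdb.fixtures import GENERALIZED_LAB, PANEL_ARCHETYPES
from armdb.query import Condition, SUBJECT, query
from armdb.synth import PANELS
from armdb.translate import (
    translate_generalized_query,
    translate_specialized_instance,
    translate_specialized_query,
)

FBC = PANEL_ARCHETYPES["full_blood_count"]
BG = PANEL_ARCHETYPES["blood_gases"]


@pytest.fixture(scope="module")
def ctx(suite):
    return {
        "gen": suite.archetype(GENERALIZED_LAB),
        "fbc": suite.archetype(FBC),
        "bg": suite.archetype(BG),
        "fbc_map": suite.mapping_for(FBC),
        "bg_map": suite.mapping_for(BG),
    }


def test_white_cell_count_condition_becomes_a_name_value_pair(ctx):
    spec = query(FBC, [Condition("whiteCellCount", "magnitude", ">=", 4)])
    out = translate_specialized_query(spec, ctx["fbc_map"], ctx["fbc"], ctx["gen"])
    (term,) = out.terms
    assert term.archetype_id == GENERALIZED_LAB
    conds = term.conditions
    assert len(conds) == 2
    name_c, value_c = conds
    assert name_c.norm_path == "[structureResult]/[testItem]" and \
        name_c.op == "=" and name_c.value == "White cell count"
    assert value_c.norm_path == "[structureResult]/[result]" and \
        value_c.op == ">=" and value_c.value == 4
    assert name_c.group == value_c.group is not None  # same repetition


def test_distinct_analytes_bind_distinct_repetitions(ctx):
    spec = query(BG, [Condition("paO2", "magnitude", ">=", 129),
                      Condition("paCO2", "magnitude", ">=", 27)])
    out = translate_specialized_query(spec, ctx["bg_map"], ctx["bg"], ctx["gen"])
    groups = {c.group for c in out.terms[0].conditions}
    assert len(groups) == 2


def test_empty_condition_set_translates_to_empty(ctx):
    out = translate_specialized_query(query(BG), ctx["bg_map"], ctx["bg"], ctx["gen"])
    assert out.terms[0].conditions == ()


def test_uncovered_path_is_untranslatable(ctx):
    spec = query(BG, [Condition("testDateTime", "value", ">=", "2014-01-01")])
    with pytest.raises(TranslationError, match="not covered"):
        translate_specialized_query(spec, ctx["bg_map"], ctx["bg"], ctx["gen"])


def test_instance_translation_builds_name_value_unit_repetitions(ctx):
    inst = ArchetypeInstance(BG, {
        "patient": {"value": "P1"},
        "paO2": {"magnitude": 140.0, "units": "mmHg"},
        "saO2": {"magnitude": 97.5, "units": "%"},
    })
    gen = translate_specialized_instance(inst, ctx["bg_map"], ctx["bg"], ctx["gen"],
                                         extra_values={"id": {"id": "G1"}})
    assert gen.archetype_id == GENERALIZED_LAB
    reps = gen.values["structureResult"]
    by_name = {r["testItem"]["value"]: r for r in reps}
    assert set(by_name) == {"PaO2", "SaO2"}
    assert by_name["PaO2"]["result"]["value"] == "140"
    assert by_name["PaO2"]["resultUnit"]["value"] == "mmHg"
    assert gen.values["patient"] == {"value": "P1"}


def _blood_gas_instances(n=120, patients=40, seed=7):
    rng = np.random.default_rng(seed)
    panel = PANELS[0]
    out = []
    for i in range(n):
        v = {"receiverOrderIdentifier": {"value": f"L{i:04d}"},
             "patient": {"value": f"P{i % patients:03d}"}}
        for a in panel.analytes:
            if rng.random() < 0.9:
                v[a.node] = {"magnitude": a.draw(rng), "units": a.units}
        out.append(ArchetypeInstance(BG, v))
    return out


def test_duality_of_storage_routes(ctx, schema, suite, suite_map):
    """Blood-gas data stored via the generalized archetype and queried with
    translated specialized specs selects the same patients as direct
    specialized storage -- and the reverse translation agrees."""
    insts = _blood_gas_instances()
    spec = query(BG, [Condition("paO2", "magnitude", ">=", 129),
                      Condition("caO2", "magnitude", ">=", 17)],
                 group_unit=SUBJECT)

    ca = sqlite3.connect(":memory:")
    specialized_store = ArmStore.deploy(schema, suite_map, ca)
    load_instances(specialized_store, insts)
    direct = specialized_store.run_query(spec)

    cb = sqlite3.connect(":memory:")
    generalized_store = ArmStore.deploy(schema, suite_map, cb)
    load_instances(generalized_store, [
        translate_specialized_instance(x, ctx["bg_map"], ctx["bg"], ctx["gen"],
                                       extra_values={"id": {"id": f"G{i:04d}"}})
        for i, x in enumerate(insts)
    ])
    translated = translate_specialized_query(spec, ctx["bg_map"], ctx["bg"], ctx["gen"])
    via_general = generalized_store.run_query(translated)
    assert direct.rows == via_general.rows and len(direct) > 0

    # reverse: the generalized query unions per-specialized translations
    reverse_specs = translate_generalized_query(translated, [ctx["bg_map"]], suite_map)
    subjects = set()
    for s in reverse_specs:
        subjects |= set(specialized_store.run_query(s).rows)
    assert sorted(subjects) == via_general.rows
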
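"""Archetype parsing, serialization and version-relationship semantics."""

import pytest

from armdb.archetype import (
    CollectionItem,
    Occurrence,
    SemanticRelationship,
    classify_relationship,
    parse_archetype,
    serialize_archetype,
)
from armdb.errors import DialectSyntaxError, LineageError

REV = SemanticRelationship.REVISION
SPEC = SemanticRelationship.SPECIALIZATION
NEWV = SemanticRelationship.NEW_VERSION


def _arch(nodes: str, aid="openEHR-EHR-OBSERVATION.demo.v1", parent=""):
    head = f"archetype_id: {aid}\n"
    if parent:
        head += f"parent_id: {parent}\n"
    return parse_archetype(head + "nodes:\n" + nodes)


BASE = """
  - {name: id, kind: basic, type: DvIdentifier, occurrence: 1..1, text: {en: Id}}
  - {name: score, kind: basic, type: DvCount, occurrence: 1..1, text: {en: Score}}
"""


def test_roundtrip_over_fixture_suite(suite):
    """parse -> serialize -> parse is the identity on all 17 fixtures."""
    for arch in suite.archetypes:
        again = parse_archetype(serialize_archetype(arch))
        assert again == arch, arch.id_text


def test_fixture_suite_is_closed(suite):
    """Every slot target and specialization parent is itself in the suite."""
    ids = set(suite.by_id)
    for arch in suite.archetypes:
        if arch.parent_id is not None:
            assert arch.parent_id.render() in ids
        for node in arch.walk():
            if hasattr(node, "target_archetype_id"):
                assert node.target_archetype_id in ids, node.target_archetype_id


def test_generalized_lab_adds_the_result_triple(suite):
    """The generalized lab archetype specializes lab_test and adds the
    repeating (Test item, Result, Result unit) group."""
    gen = suite.archetype("openEHR-EHR-OBSERVATION.lab_test-general.v1")
    assert gen.parent_id.render() == "openEHR-EHR-OBSERVATION.lab_test.v1"
    group = gen.node_at("[structureResult]")
    assert isinstance(group, CollectionItem) and group.occurrence.is_many
    names = [gen.display_text(c.path) for c in group.children]
    assert names == ["Test item", "Result", "Result unit"]


@pytest.mark.parametrize("bad,match", [
    ("archetype_id: openEHR-EHR-OBSERVATION.demo.v1\nnodes: []\n", "empty archetype"),
    ("archetype_id: bad-id\nnodes:\n" + BASE, "bad archetype id"),
    ("archetype_id: openEHR-EHR-OBSERVATION.demo.v1\nnodes:\n"
     "  - {name: x, kind: basic, type: DvWrong, occurrence: 1..1, text: {en: X}}\n",
     "unknown basic type"),
    ("archetype_id: openEHR-EHR-OBSERVATION.demo.v1\nnodes:\n"
     "  - {name: x, kind: basic, type: DvText, occurrence: 1..1, text: {en: X}}\n"
     "  - {name: x, kind: basic, type: DvText, occurrence: 1..1, text: {en: X}}\n",
     "duplicate path"),
    ("archetype_id: openEHR-EHR-OBSERVATION.demo.v1\n"
     "parent_id: openEHR-EHR-OBSERVATION.other.v1\nnodes:\n" + BASE,
     "does not specialize"),
    ("archetype_id: openEHR-EHR-OBSERVATION.demo.v1\nnodes:\n"
     "  - {name: c, kind: cluster, occurrence: 1..1, text: {en: C}, children: []}\n",
     "no children"),
], ids=["empty", "bad-id", "unknown-type", "dup-path", "bad-parent", "empty-cluster"])
def test_malformed_definitions_are_rejected(bad, match):
    with pytest.raises(DialectSyntaxError, match=match):
        parse_archetype(bad)


def test_syntax_errors_report_position():
    with pytest.raises(DialectSyntaxError, match="line"):
        parse_archetype("archetype_id: [unclosed\n  - oops\n")


def test_occurrence_forms():
    assert Occurrence.parse("0..*").is_many
    assert not Occurrence.parse("1..1").is_many and Occurrence.parse("1..1").mandatory
    for bad in ("2..1", "0..2", "1", "*..1"):
        with pytest.raises(DialectSyntaxError):
            Occurrence.parse(bad)


def test_identity_classifies_as_revision(suite):
    """Compatibility trivially holds for identical definitions."""
    for arch in suite.archetypes:
        assert classify_relationship(arch, arch) is REV


def test_adding_an_optional_item_is_a_revision():
    old = _arch(BASE)
    new = _arch(BASE + "  - {name: note, kind: basic, type: DvText, occurrence: 0..1, text: {en: Note}}\n")
    assert classify_relationship(old, new) is REV


def test_widening_upper_bound_is_a_revision():
    old = _arch(BASE)
    new = _arch(BASE.replace("score, kind: basic, type: DvCount, occurrence: 1..1",
                             "score, kind: basic, type: DvCount, occurrence: 1..*"))
    assert classify_relationship(old, new) is REV


@pytest.mark.parametrize("mutate", [
    # mandatory item becomes optional
    lambda t: t.replace("score, kind: basic, type: DvCount, occurrence: 1..1",
                        "score, kind: basic, type: DvCount, occurrence: 0..1"),
    # data type change
    lambda t: t.replace("type: DvCount", "type: DvQuantity"),
    # item removed
    lambda t: t.replace(
        "  - {name: score, kind: basic, type: DvCount, occurrence: 1..1, text: {en: Score}}\n",
        ""),
], ids=["mandatory-to-optional", "type-change", "removal"])
def test_incompatible_changes_are_new_versions(mutate):
    old = _arch(BASE)
    new = _arch(mutate(BASE))
    assert classify_relationship(old, new) is NEWV


def test_specialization_of_the_lab_lineage(suite):
    lab = suite.archetype("openEHR-EHR-OBSERVATION.lab_test.v1")
    for concept in ("general", "blood_gases"):
        sub = suite.archetype(f"openEHR-EHR-OBSERVATION.lab_test-{concept}.v1")
        assert classify_relationship(lab, sub) is SPEC


def test_unrelated_concepts_have_no_lineage():
    a = _arch(BASE, aid="openEHR-EHR-OBSERVATION.alpha.v1")
    b = _arch(BASE, aid="openEHR-EHR-OBSERVATION.beta.v1")
    with pytest.raises(LineageError, match="no lineage"):
        classify_relationship(a, b)
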
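"""Templates with ARM persistence constraints, and generalized/specialized
EAV mappings.

A template localizes one archetype (one template per archetype) and carries
the ARM constraints that drive index generation:

* the identification data item (IDI) -- at most one, a basic item with
  occurrence 0..1 or 1..1, mapped to the unique clustered key;
* query data items (QDIs) -- basic items mapped to non-clustered indexes and
  propagated into the child tables of multiple-occurrence slots/collections
  unless explicitly suppressed.

EAV mappings relate a specialized archetype (e.g. a blood-gas panel) to the
generalized name/value/unit archetype, using the XML element vocabulary
``<eav>``, ``<eavAttributeName>``, ``<eavAttributeField>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml
from lxml import etree

from .archetype import (
    Archetype,
    BasicItem,
    CollectionItem,
    Occurrence,
    normalize_path,
)
from .errors import DialectSyntaxError

# -- templates -------------------------------------------------------------


@dataclass
class ArmConstraints:
    identification_item: Optional[str] = None  # node path
    query_items: list[str] = field(default_factory=list)
    #: (slot-or-collection path, query-item path) pairs whose rule-7
    #: propagation is disregarded
    suppressed_propagations: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Template:
    template_id: str
    archetype_id: str
    arm: ArmConstraints
    optionality_overrides: dict[str, Occurrence] = field(default_factory=dict)
    default_values: dict[str, object] = field(default_factory=dict)
    slot_fills: dict[str, str] = field(default_factory=dict)


def parse_template(definition_text: str) -> Template:
    """Parse a template dialect document (YAML).

    Reference errors against the archetype are deferred to
    :func:`validate_template`; only document-local invariants (single IDI)
    are enforced here.
    """
    try:
        doc = yaml.safe_load(definition_text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        pos = f"line {mark.line + 1}, column {mark.column + 1}" if mark else None
        raise DialectSyntaxError(f"invalid YAML: {exc}", position=pos) from None
    if not isinstance(doc, dict):
        raise DialectSyntaxError("template document must be a mapping")
    for key in ("template_id", "archetype_id"):
        if key not in doc:
            raise DialectSyntaxError(f"template missing {key}")
    arm_doc = doc.get("arm") or {}
    idi = arm_doc.get("identification_item")
    if isinstance(idi, list):
        raise DialectSyntaxError("a template may declare only one identification data item")
    qdis = arm_doc.get("query_items") or []
    suppressed = [tuple(pair) for pair in (arm_doc.get("suppressed_propagations") or [])]
    for pair in suppressed:
        if len(pair) != 2:
            raise DialectSyntaxError(f"bad suppressed propagation entry {pair!r}")
    overrides = {
        str(p): Occurrence.parse(str(o))
        for p, o in (doc.get("optionality_overrides") or {}).items()
    }
    return Template(
        template_id=str(doc["template_id"]),
        archetype_id=str(doc["archetype_id"]),
        arm=ArmConstraints(
            identification_item=str(idi) if idi else None,
            query_items=[str(q) for q in qdis],
            suppressed_propagations=[(str(a), str(b)) for a, b in suppressed],
        ),
        optionality_overrides=overrides,
        default_values=dict(doc.get("default_values") or {}),
        slot_fills={str(k): str(v) for k, v in (doc.get("slot_fills") or {}).items()},
    )


def serialize_template(t: Template) -> str:
    doc: dict = {
        "template_id": t.template_id,
        "archetype_id": t.archetype_id,
        "arm": {
            "identification_item": t.arm.identification_item,
            "query_items": list(t.arm.query_items),
            "suppressed_propagations": [list(p) for p in t.arm.suppressed_propagations],
        },
    }
    if t.optionality_overrides:
        doc["optionality_overrides"] = {p: o.render() for p, o in t.optionality_overrides.items()}
    if t.default_values:
        doc["default_values"] = dict(t.default_values)
    if t.slot_fills:
        doc["slot_fills"] = dict(t.slot_fills)
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def validate_template(template: Template, archetype: Archetype, suite=None) -> list[str]:
    """Check ARM constraints against the archetype tree.

    Returns a list of violation messages; an empty list means the template is
    valid.  Violations are data, not exceptions.  When the archetype suite is
    supplied, paths resolve through single-occurrence slots (the expanded
    tree); otherwise only the archetype's own nodes are visible.
    """
    violations: list[str] = []
    if template.archetype_id != archetype.id_text:
        violations.append(
            f"template {template.template_id} is bound to {template.archetype_id}, "
            f"not {archetype.id_text}"
        )
        return violations

    from .archetype import coerce_path

    if suite is not None:
        from .mapper import effective_tree  # deferred: mapper imports this module

        suite_map = suite if isinstance(suite, dict) else {a.id_text: a for a in suite}
        nodes, _onto, _emb = effective_tree(archetype, suite_map)
        by_path: dict = {}

        def index(ns):
            for n in ns:
                by_path[n.path] = n
                if isinstance(n, CollectionItem):
                    index(n.children)

        index(nodes)

        def resolve(path):
            return by_path.get(coerce_path(path))

    else:

        def resolve(path):
            try:
                return archetype.node_at(coerce_path(path))
            except KeyError:
                return None

    idi = template.arm.identification_item
    if idi is not None:
        node = resolve(idi)
        if node is None:
            violations.append(f"identification item {idi!r} not found in archetype")
        elif not isinstance(node, BasicItem):
            violations.append(
                f"identification item {idi!r} is a collection or slot; "
                "only basic data items may identify instances"
            )
        elif node.occurrence.is_many:
            violations.append(
                f"identification item {idi!r} has occurrence "
                f"{node.occurrence.render()}; 0..1 or 1..1 required"
            )
    for q in template.arm.query_items:
        node = resolve(q)
        if node is None:
            violations.append(f"query item {q!r} not found in archetype")
        elif not isinstance(node, BasicItem):
            violations.append(f"query item {q!r} is a collection or slot")
    for group_path, q in template.arm.suppressed_propagations:
        node = resolve(group_path)
        if node is None or isinstance(node, BasicItem):
            violations.append(f"suppression target {group_path!r} is not a slot/collection")
        if q not in template.arm.query_items:
            violations.append(f"suppressed propagation names non-query item {q!r}")
    for path, occ in template.optionality_overrides.items():
        node = resolve(path)
        if node is None:
            violations.append(f"optionality override path {path!r} not found")
            continue
        base = node.occurrence
        if occ.lower < base.lower or (base.upper == "1" and occ.upper == "*"):
            violations.append(
                f"override {path!r} loosens occurrence {base.render()} -> {occ.render()}"
            )
    for slot_path, target in template.slot_fills.items():
        node = resolve(slot_path)
        if node is None or isinstance(node, (BasicItem, CollectionItem)):
            violations.append(f"slot fill path {slot_path!r} is not a slot")
    return violations


# -- EAV mappings ----------------------------------------------------------


@dataclass(frozen=True)
class NameEntry:
    source_item_path: str  # e.g. "[White cell count]"
    language_set: str  # e.g. "en"
    target_name_path: str  # e.g. "[Test item]/value/value"


@dataclass(frozen=True)
class FieldEntry:
    source_field_path: str  # e.g. "[White cell count]/value/magnitude"
    target_field_path: str  # e.g. "[Result]/value/value"


@dataclass
class EavMapping:
    specialized_archetype_id: str
    generalized_archetype_id: str
    name_entries: list[NameEntry] = field(default_factory=list)
    field_entries: list[FieldEntry] = field(default_factory=list)


def _norm_eav_path(text: str) -> str:
    """Normalize a Table-4 style path: trim whitespace inside brackets and
    around '/'; never change letter case."""
    text = (text or "").strip()
    if not text:
        return ""
    parts = [p.strip() for p in text.split("/")]
    out = []
    for p in parts:
        if p.startswith("[") and p.endswith("]"):
            out.append(f"[{p[1:-1].strip()}]")
        else:
            out.append(p)
    return "/".join(out)


_EAV_ELEMENTS = {"eav", "eavAttributeName", "eavAttributeField"}


def parse_eav_mapping(xml_text: str, specialized_archetype_id: str) -> EavMapping:
    """Parse an EAV mapping document.

    The document is a flat sequence of ``<eav>``, ``<eavAttributeName>`` and
    ``<eavAttributeField>`` elements (a synthetic root is tolerated).  The
    ``<eav>`` element names the generalized target archetype; each name entry
    maps a specialized item's display name, each field entry one of its
    fields.
    """
    text = xml_text.strip()
    try:
        root = etree.fromstring(f"<_armdb_root>{text}</_armdb_root>".encode())
    except etree.XMLSyntaxError as exc:
        raise DialectSyntaxError(f"invalid XML: {exc}") from None

    generalized: Optional[str] = None
    names: list[NameEntry] = []
    fields: list[FieldEntry] = []
    for el in root:
        if el.tag not in _EAV_ELEMENTS:
            raise DialectSyntaxError(f"unknown element <{el.tag}>")
        name_attr = el.get("name")
        if name_attr is None:
            raise DialectSyntaxError(f"<{el.tag}> missing name attribute")
        if el.tag == "eav":
            generalized = name_attr.strip()
        elif el.tag == "eavAttributeName":
            names.append(
                NameEntry(
                    source_item_path=_norm_eav_path(name_attr),
                    language_set=(el.get("set") or "en").strip(),
                    target_name_path=_norm_eav_path(el.text or ""),
                )
            )
        else:
            fields.append(
                FieldEntry(
                    source_field_path=_norm_eav_path(name_attr),
                    target_field_path=_norm_eav_path(el.text or ""),
                )
            )
    if generalized is None:
        raise DialectSyntaxError("mapping document has no <eav> element")
    return EavMapping(specialized_archetype_id, generalized, names, fields)


def serialize_eav_mapping(m: EavMapping) -> str:
    lines = [f'<eav name="{m.generalized_archetype_id}"></eav>']
    for ne in m.name_entries:
        lines.append(
            f'<eavAttributeName name="{ne.source_item_path}" set="{ne.language_set}">'
            f"{ne.target_name_path}</eavAttributeName>"
        )
    for fe in m.field_entries:
        lines.append(
            f'<eavAttributeField name="{fe.source_field_path}">'
            f"{fe.target_field_path}</eavAttributeField>"
        )
    return "\n".join(lines) + "\n"


def _split_eav_path(path: str) -> tuple[str, Optional[str]]:
    """Split "[Name]/value/field" into the bracketed item part and field name."""
    parts = path.split("/")
    item_parts = [p for p in parts if p.startswith("[")]
    tail = [p for p in parts if not p.startswith("[")]
    field_name = tail[-1] if tail else None
    return "/".join(item_parts), field_name


def validate_eav_mapping(
    mapping: EavMapping, specialized: Archetype, generalized: Archetype
) -> list[str]:
    """Check that source paths exist in the specialized archetype and target
    paths resolve to basic items of one multiple-occurrence group of the
    generalized archetype."""
    violations: list[str] = []
    if mapping.generalized_archetype_id != generalized.id_text:
        violations.append(
            f"mapping targets {mapping.generalized_archetype_id}, not {generalized.id_text}"
        )
        return violations

    group_paths: set[str] = set()

    def check_target(path: str, what: str):
        item_path, _fld = _split_eav_path(path)
        display = item_path.split("/")[-1][1:-1] if item_path else ""
        try:
            node = generalized.find_by_display(display)
        except KeyError:
            violations.append(f"{what} target {path!r} absent from generalized archetype")
            return
        # locate nearest multiple-occurrence ancestor
        anchor = None
        for cand in generalized.walk():
            if isinstance(cand, CollectionItem) and cand.occurrence.is_many:
                if node.path.startswith(cand.path + "/"):
                    anchor = cand.path
        if anchor is None:
            violations.append(f"{what} target {path!r} is not inside a multiple-occurrence group")
        else:
            group_paths.add(anchor)

    for ne in mapping.name_entries:
        display = ne.source_item_path.split("/")[-1][1:-1] if ne.source_item_path else ""
        try:
            specialized.find_by_display(display, ne.language_set)
        except KeyError:
            violations.append(f"name entry source {ne.source_item_path!r} absent from specialized")
        check_target(ne.target_name_path, "name entry")

    per_item_targets: dict[str, set[str]] = {}
    for fe in mapping.field_entries:
        src_item, _src_field = _split_eav_path(fe.source_field_path)
        display = src_item.split("/")[-1][1:-1] if src_item else ""
        try:
            specialized.find_by_display(display)
        except KeyError:
            violations.append(
                f"field entry source {fe.source_field_path!r} absent from specialized"
            )
        check_target(fe.target_field_path, "field entry")
        targets = per_item_targets.setdefault(src_item, set())
        if fe.target_field_path in targets:
            violations.append(
                f"item {src_item!r} maps two source fields to {fe.target_field_path!r}"
            )
        targets.add(fe.target_field_path)

    if len(group_paths) > 1:
        violations.append(
            f"mapping targets span several multiple-occurrence groups: {sorted(group_paths)}"
        )
    return violations


__all__ = [
    "ArmConstraints",
    "Template",
    "EavMapping",
    "NameEntry",
    "FieldEntry",
    "parse_template",
    "serialize_template",
    "validate_template",
    "parse_eav_mapping",
    "serialize_eav_mapping",
    "validate_eav_mapping",
    "normalize_path",
]
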
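"""Archetype model: data-item trees, occurrences, parsing, version semantics.

An archetype is a named tree of data items constraining one clinical concept.
Leaves (basic items) carry a basic data type; collections (CLUSTER /
ITEM_TREE / ITEM_LIST) group items; slots plug another archetype in.  Every
node has an occurrence (0..1, 1..1, 0..* or 1..*) and an ontology display
text per language.

Archetypes are interchanged as small YAML documents (one per file); the
dialect captures exactly the fields of this model and nothing of full ADL.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Union

import yaml

from .errors import DialectSyntaxError, LineageError, ValidationError
from .types import BASIC_TYPES

ONE = "1"
MANY = "*"


@dataclass(frozen=True)
class Occurrence:
    lower: int  # 0 or 1
    upper: str  # ONE or MANY

    def __post_init__(self):
        if self.lower not in (0, 1) or self.upper not in (ONE, MANY):
            raise ValidationError(f"invalid occurrence {self.lower}..{self.upper}")

    @property
    def is_many(self) -> bool:
        return self.upper == MANY

    @property
    def mandatory(self) -> bool:
        return self.lower == 1

    def render(self) -> str:
        return f"{self.lower}..{self.upper}"

    @classmethod
    def parse(cls, text: str) -> "Occurrence":
        try:
            lo, up = text.split("..")
            return cls(int(lo), up)
        except (ValueError, ValidationError):
            raise DialectSyntaxError(f"bad occurrence {text!r}") from None


OPTIONAL = Occurrence(0, ONE)
REQUIRED = Occurrence(1, ONE)
OPTIONAL_MANY = Occurrence(0, MANY)
REQUIRED_MANY = Occurrence(1, MANY)

COLLECTION_KINDS = ("CLUSTER", "ITEM_TREE", "ITEM_LIST")


@dataclass(frozen=True)
class BasicItem:
    name: str
    path: str
    type_name: str
    occurrence: Occurrence


@dataclass(frozen=True)
class CollectionItem:
    name: str
    path: str
    kind: str  # one of COLLECTION_KINDS
    children: tuple["DataNode", ...]
    occurrence: Occurrence


@dataclass(frozen=True)
class SlotItem:
    name: str
    path: str
    target_archetype_id: str
    occurrence: Occurrence


DataNode = Union[BasicItem, CollectionItem, SlotItem]


@dataclass(frozen=True)
class ArchetypeId:
    """Identifier of the form openEHR-<domain>-<class>.<concept>.v<N>."""

    rm_domain: str
    rm_class: str
    concept_name: str
    version: int

    def render(self) -> str:
        return f"openEHR-{self.rm_domain}-{self.rm_class}.{self.concept_name}.v{self.version}"

    @property
    def versionless(self) -> str:
        return f"openEHR-{self.rm_domain}-{self.rm_class}.{self.concept_name}"

    @classmethod
    def parse(cls, text: str) -> "ArchetypeId":
        try:
            head, concept, vpart = text.split(".")
            prefix, domain, rm_class = head.split("-", 2)
            if prefix != "openEHR" or not vpart.startswith("v"):
                raise ValueError
            version = int(vpart[1:])
            if version < 1:
                raise ValueError
        except ValueError:
            raise DialectSyntaxError(f"bad archetype id {text!r}") from None
        return cls(domain, rm_class, concept, version)


@dataclass
class Archetype:
    archetype_id: ArchetypeId
    root_nodes: tuple[DataNode, ...]
    parent_id: Optional[ArchetypeId] = None
    ontology: dict[str, dict[str, str]] = field(default_factory=dict)  # path -> {lang: text}

    @property
    def id_text(self) -> str:
        return self.archetype_id.render()

    # -- tree helpers -----------------------------------------------------

    def walk(self) -> Iterator[DataNode]:
        """All nodes in document order (depth first)."""

        def rec(nodes):
            for n in nodes:
                yield n
                if isinstance(n, CollectionItem):
                    yield from rec(n.children)

        yield from rec(self.root_nodes)

    def node_at(self, path: str) -> DataNode:
        for n in self.walk():
            if n.path == path:
                return n
        raise KeyError(f"{self.id_text}: no node at path {path!r}")

    def display_text(self, path: str, lang: str = "en") -> str:
        texts = self.ontology.get(path, {})
        if lang in texts:
            return texts[lang]
        if texts:
            return next(iter(texts.values()))
        raise KeyError(f"{self.id_text}: no ontology text for {path!r}")

    def find_by_display(self, display: str, lang: str = "en") -> DataNode:
        for n in self.walk():
            if self.ontology.get(n.path, {}).get(lang) == display:
                return n
        raise KeyError(f"{self.id_text}: no node with display text {display!r}")


def node_path(parent_path: str, name: str) -> str:
    seg = f"[{name}]"
    return f"{parent_path}/{seg}" if parent_path else seg


def path_segments(path: str) -> list[str]:
    """Node names along a bracketed path ("[a]/[b]" -> ["a", "b"])."""
    if not path:
        return []
    segs = []
    for part in path.split("/"):
        part = part.strip()
        if not (part.startswith("[") and part.endswith("]")):
            raise DialectSyntaxError(f"bad path segment {part!r} in {path!r}")
        segs.append(part[1:-1].strip())
    return segs


def normalize_path(path: str) -> str:
    """Canonical rendering: trimmed segment text, '/'-joined brackets."""
    return "/".join(f"[{s}]" for s in path_segments(path))


def names_to_path(names: list[str]) -> str:
    return "/".join(f"[{n}]" for n in names)


def coerce_path(path: str) -> str:
    """Canonical bracketed path from either dialect ("a/b" or "[a]/[b]")."""
    if "[" in path:
        return normalize_path(path)
    return names_to_path([p.strip() for p in path.split("/") if p.strip()])


# -- parsing ---------------------------------------------------------------


def _parse_node(doc: dict, parent_path: str, where: str) -> DataNode:
    if not isinstance(doc, dict):
        raise DialectSyntaxError(f"node must be a mapping at {where}")
    try:
        name = doc["name"]
        kind = doc["kind"]
    except (KeyError, TypeError):
        raise DialectSyntaxError(f"node missing name/kind at {where}") from None
    occ = Occurrence.parse(str(doc.get("occurrence", "0..1")))
    path = node_path(parent_path, name)
    if kind == "basic":
        type_name = doc.get("type")
        if type_name not in BASIC_TYPES:
            raise DialectSyntaxError(f"unknown basic type name {type_name!r} at {path}")
        return BasicItem(name, path, type_name, occ)
    if kind in ("cluster", "item_tree", "item_list"):
        children = doc.get("children") or []
        if not children:
            raise DialectSyntaxError(f"collection {path} has no children")
        parsed = tuple(_parse_node(c, path, path) for c in children)
        return CollectionItem(name, path, kind.upper(), parsed, occ)
    if kind == "slot":
        target = doc.get("target")
        if not target:
            raise DialectSyntaxError(f"slot {path} missing target")
        ArchetypeId.parse(target)
        return SlotItem(name, path, target, occ)
    raise DialectSyntaxError(f"unknown node kind {kind!r} at {path}")


def _collect_ontology(doc_nodes, parent_path, ontology, where="root"):
    for nd in doc_nodes or []:
        if not isinstance(nd, dict) or "name" not in nd:
            continue  # structural errors reported by _parse_node
        path = node_path(parent_path, nd["name"])
        text = nd.get("text") or {}
        if not isinstance(text, dict) or not text:
            raise DialectSyntaxError(f"node {path} has no ontology text")
        ontology[path] = {str(k): str(v) for k, v in text.items()}
        if nd.get("children"):
            _collect_ontology(nd["children"], path, ontology, path)


def parse_archetype(definition_text: str) -> Archetype:
    """Parse an archetype dialect document (YAML, one archetype per file)."""
    try:
        doc = yaml.safe_load(definition_text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        pos = f"line {mark.line + 1}, column {mark.column + 1}" if mark else None
        raise DialectSyntaxError(f"invalid YAML: {exc}", position=pos) from None
    if not isinstance(doc, dict):
        raise DialectSyntaxError("archetype document must be a mapping")
    if "archetype_id" not in doc:
        raise DialectSyntaxError("missing archetype_id")
    aid = ArchetypeId.parse(str(doc["archetype_id"]))
    parent = ArchetypeId.parse(str(doc["parent_id"])) if doc.get("parent_id") else None
    nodes_doc = doc.get("nodes") or []
    if not nodes_doc:
        raise DialectSyntaxError("empty archetype: no data nodes")
    nodes = tuple(_parse_node(n, "", "root") for n in nodes_doc)
    ontology: dict[str, dict[str, str]] = {}
    _collect_ontology(nodes_doc, "", ontology)
    arch = Archetype(aid, nodes, parent, ontology)
    _validate(arch)
    return arch


def _validate(arch: Archetype) -> None:
    seen: set[str] = set()
    for n in arch.walk():
        if n.path in seen:
            raise DialectSyntaxError(f"duplicate path {n.path!r} in {arch.id_text}")
        seen.add(n.path)
        if n.path not in arch.ontology:
            raise DialectSyntaxError(f"node {n.path} has no ontology text")
    if arch.parent_id is not None:
        pc = arch.parent_id.concept_name
        cc = arch.archetype_id.concept_name
        if not cc.startswith(pc + "-"):
            raise DialectSyntaxError(
                f"{arch.id_text}: concept {cc!r} does not specialize parent concept {pc!r}"
            )


# -- serialization ---------------------------------------------------------


def _node_to_doc(node: DataNode, ontology) -> dict:
    doc: dict = {"name": node.name}
    if isinstance(node, BasicItem):
        doc["kind"] = "basic"
        doc["type"] = node.type_name
    elif isinstance(node, CollectionItem):
        doc["kind"] = node.kind.lower()
    else:
        doc["kind"] = "slot"
        doc["target"] = node.target_archetype_id
    doc["occurrence"] = node.occurrence.render()
    doc["text"] = dict(ontology.get(node.path, {}))
    if isinstance(node, CollectionItem):
        doc["children"] = [_node_to_doc(c, ontology) for c in node.children]
    return doc


def serialize_archetype(arch: Archetype) -> str:
    doc = {
        "archetype_id": arch.id_text,
        "parent_id": arch.parent_id.render() if arch.parent_id else None,
        "nodes": [_node_to_doc(n, arch.ontology) for n in arch.root_nodes],
    }
    if doc["parent_id"] is None:
        del doc["parent_id"]
    buf = io.StringIO()
    yaml.safe_dump(doc, buf, sort_keys=False, allow_unicode=True)
    return buf.getvalue()


# -- version semantics -----------------------------------------------------


class SemanticRelationship(enum.Enum):
    REVISION = "REVISION"
    SPECIALIZATION = "SPECIALIZATION"
    NEW_VERSION = "NEW_VERSION"


def _occurrence_compatible(old: Occurrence, new: Occurrence) -> bool:
    """Is data created under ``old`` acceptable under ``new``?

    Widening the upper bound (1 -> *) keeps old data valid.  Turning a
    mandatory item optional, or narrowing * -> 1, changes the contract the
    stored data relies on and is treated as an incompatible change.
    """
    if old.lower == 1 and new.lower == 0:
        return False  # mandatory item became optional
    if old.lower == 0 and new.lower == 1:
        return False  # constraint narrowed: old sparse data may violate it
    if old.upper == MANY and new.upper == ONE:
        return False  # repetitions no longer representable
    return True


def classify_relationship(old: Archetype, new: Archetype) -> SemanticRelationship:
    """Classify the change from ``old`` to ``new`` (revision / specialization /
    new version), following the openEHR compatibility semantics."""
    oc = old.archetype_id.concept_name
    nc = new.archetype_id.concept_name
    specializes = nc.startswith(oc + "-")
    if nc != oc and not specializes:
        raise LineageError(f"no lineage between {old.id_text} and {new.id_text}")

    old_nodes = {n.path: n for n in old.walk()}
    new_nodes = {n.path: n for n in new.walk()}
    compatible = True
    for path, onode in old_nodes.items():
        nnode = new_nodes.get(path)
        if nnode is None or type(nnode) is not type(onode):
            compatible = False
            break
        if isinstance(onode, BasicItem) and onode.type_name != nnode.type_name:
            compatible = False
            break
        if isinstance(onode, SlotItem) and onode.target_archetype_id != nnode.target_archetype_id:
            compatible = False
            break
        if specializes:
            # a specialization may only keep or strengthen occurrences
            if nnode.occurrence.lower < onode.occurrence.lower:
                compatible = False
                break
            if onode.occurrence.upper == ONE and nnode.occurrence.upper == MANY:
                compatible = False
                break
        elif not _occurrence_compatible(onode.occurrence, nnode.occurrence):
            compatible = False
            break

    if specializes:
        if not compatible:
            return SemanticRelationship.NEW_VERSION
        return SemanticRelationship.SPECIALIZATION
    return SemanticRelationship.REVISION if compatible else SemanticRelationship.NEW_VERSION


def with_nodes(arch: Archetype, nodes: tuple[DataNode, ...], **id_changes) -> Archetype:
    """Convenience for building modified copies in version experiments."""
    aid = replace(arch.archetype_id, **id_changes) if id_changes else arch.archetype_id
    return Archetype(aid, nodes, arch.parent_id, dict(arch.ontology))
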
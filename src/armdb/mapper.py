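"""Archetype-to-relational schema mapping.

Applies the ARM rules to a set of archetypes, templates and EAV mappings:

1. each (tabled) archetype maps to a table; compatible revisions of one
   archetype share a table;
2. single-occurrence basic items become columns, multiple-occurrence basic
   items become standalone tables with a foreign key to the archetype key;
3. the identification data item carries the unique clustered index; without
   one, an invisible generated ``id`` key is added;
4. query data items carry non-clustered indexes;
5. a multiple-occurrence slot becomes a foreign-key column in the *target*
   archetype's table; a single-occurrence slot embeds the target's items
   into the current table;
6. single-occurrence collections are flattened; multiple-occurrence
   collections become standalone tables with a foreign key;
7. query data items (like the identification item) propagate into the
   standalone tables of multiple-occurrence slots/collections as
   non-clustered-indexed columns, unless suppressed in the template;
8. names derive from archetype/data-item names (rm-class prefix letter +
   CamelCase concept), version-stripped for shared tables, and are shortened
   deterministically when they exceed the identifier limit.

Not every archetype yields a table: archetypes used purely as
single-occurrence slot fillers are embedded where they are used, and
abstract generalization parents carry no data of their own.  A table is
created for every archetype that has a template, that is the specialized
side of an EAV mapping, or that is the target of a multiple-occurrence slot
of a tabled archetype.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .archetype import (
    Archetype,
    ArchetypeId,
    BasicItem,
    CollectionItem,
    DataNode,
    SemanticRelationship,
    SlotItem,
    classify_relationship,
    coerce_path,
    names_to_path,
    normalize_path,
    path_segments,
)
from .errors import MappingError, MigrationError, SlotCycleError
from .template import Template, validate_template
from .types import INTEGER, resolve_field_columns

# column roles
DATA = "DATA"
GENERATED_ID = "GENERATED_ID"
FOREIGN_KEY = "FOREIGN_KEY"
PROPAGATED_QUERY = "PROPAGATED_QUERY"

# table origins
ARCHETYPE_MAIN = "ARCHETYPE_MAIN"
COLLECTION = "COLLECTION"
MULTI_ITEM = "MULTI_ITEM"

# version strategies
TABLE_PER_VERSION = "TABLE_PER_VERSION"
MERGE_AND_CONVERT = "MERGE_AND_CONVERT"

GENERATED = ("generated",)

DEFAULT_PREFIX_LETTERS = {
    "OBSERVATION": "O",
    "INSTRUCTION": "I",
    "PERSON": "D",  # demographic person
    "CLUSTER": "C",
}


@dataclass
class MapperConfig:
    name_limit: int = 64
    prefix_letters: dict = field(default_factory=lambda: dict(DEFAULT_PREFIX_LETTERS))
    #: "name": columns from data-item names along the path; "path": columns
    #: from the full bracketed path text
    column_mode: str = "name"
    dv_proportion_extended: bool = False
    version_strategy: str = TABLE_PER_VERSION
    #: queries over archetypes that are both standalone and embedded default
    #: to the standalone table only ("standalone"); "all" widens to every
    #: containing table
    division_query_scope: str = "standalone"


@dataclass
class ColumnDef:
    name: str
    storage_kind: str
    nullable: bool = True
    role: str = DATA
    #: ("data", archetype_id, node_path, field_suffix) for DATA columns,
    #: ("generated",) for generated keys/ordinals,
    #: ("fk", parent_archetype_id) / ("propagated", parent_archetype_id,
    #: node_path, field_suffix) for structural columns
    provenance: tuple = GENERATED


@dataclass(frozen=True)
class IndexDef:
    columns: tuple
    clustered: bool = False
    unique: bool = False


@dataclass(frozen=True)
class ForeignKeyDef:
    column: str
    target_table: str
    target_column: str


@dataclass
class TableDef:
    name: str
    origin: str
    source_archetype_ids: list = field(default_factory=list)
    columns: list = field(default_factory=list)
    indexes: list = field(default_factory=list)
    foreign_keys: list = field(default_factory=list)
    key_column: str = "id"
    key_generated: bool = True
    ordinal_column: Optional[str] = None
    subject_column: Optional[str] = None
    #: MANY group node path -> child table name (for tables owning groups)
    group_tables: dict = field(default_factory=dict)
    #: slot path -> (target archetype id, fk column name in target table)
    slot_children: dict = field(default_factory=dict)
    #: for child tables: (parent table, fk column, group path in host archetype)
    parent_table: Optional[str] = None
    fk_column: Optional[str] = None
    group_path: Optional[str] = None
    embedded_archetype_ids: list = field(default_factory=list)

    def column(self, name: str) -> ColumnDef:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(f"table {self.name} has no column {name!r}")

    def has_column(self, name: str) -> bool:
        return any(c.name == name for c in self.columns)

    def indexed_columns(self, clustered: Optional[bool] = None) -> set:
        out = set()
        for ix in self.indexes:
            if clustered is None or ix.clustered == clustered:
                out.update(ix.columns)
        return out


@dataclass
class RelationalSchema:
    tables: dict = field(default_factory=dict)  # name -> TableDef
    #: (archetype_id, node_path, field_suffix) -> (table, column)
    provenance: dict = field(default_factory=dict)
    #: archetype id -> main table name
    archetype_tables: dict = field(default_factory=dict)
    #: versionless archetype id -> main table name
    version_registry: dict = field(default_factory=dict)
    config: MapperConfig = field(default_factory=MapperConfig)

    def table_for(self, archetype_id: str) -> TableDef:
        try:
            return self.tables[self.archetype_tables[archetype_id]]
        except KeyError:
            raise MappingError(f"no table mapped for archetype {archetype_id}") from None

    def resolve(self, archetype_id: str, path: str, suffix: str) -> tuple:
        """(table, column) owning the leaf field at ``path``/``suffix``."""
        key = (archetype_id, coerce_path(path), suffix)
        try:
            return self.provenance[key]
        except KeyError:
            raise MappingError(
                f"no column for {archetype_id} {path!r} field {suffix!r}"
            ) from None

    # -- serialization (golden-schema format) -----------------------------

    def to_dict(self) -> dict:
        def col(c):
            return {
                "name": c.name,
                "storage_kind": c.storage_kind,
                "nullable": c.nullable,
                "role": c.role,
                "provenance": list(c.provenance),
            }

        def tab(t):
            return {
                "name": t.name,
                "origin": t.origin,
                "source_archetype_ids": list(t.source_archetype_ids),
                "columns": [col(c) for c in t.columns],
                "indexes": [
                    {"columns": list(ix.columns), "clustered": ix.clustered, "unique": ix.unique}
                    for ix in t.indexes
                ],
                "foreign_keys": [
                    {"column": fk.column, "target_table": fk.target_table,
                     "target_column": fk.target_column}
                    for fk in t.foreign_keys
                ],
                "key_column": t.key_column,
                "key_generated": t.key_generated,
                "ordinal_column": t.ordinal_column,
                "subject_column": t.subject_column,
                "group_tables": dict(t.group_tables),
                "slot_children": {k: list(v) for k, v in t.slot_children.items()},
                "parent_table": t.parent_table,
                "fk_column": t.fk_column,
                "group_path": t.group_path,
                "embedded_archetype_ids": list(t.embedded_archetype_ids),
            }

        return {
            "tables": [tab(t) for t in self.tables.values()],
            "provenance": [
                {"archetype_id": k[0], "path": k[1], "field": k[2],
                 "table": v[0], "column": v[1]}
                for k, v in sorted(self.provenance.items())
            ],
            "archetype_tables": dict(self.archetype_tables),
            "version_registry": dict(self.version_registry),
        }

    @classmethod
    def from_dict(cls, doc: dict, config: Optional[MapperConfig] = None) -> "RelationalSchema":
        schema = cls(config=config or MapperConfig())
        for td in doc["tables"]:
            t = TableDef(
                name=td["name"],
                origin=td["origin"],
                source_archetype_ids=list(td["source_archetype_ids"]),
                columns=[
                    ColumnDef(c["name"], c["storage_kind"], c["nullable"], c["role"],
                              tuple(c["provenance"]))
                    for c in td["columns"]
                ],
                indexes=[
                    IndexDef(tuple(ix["columns"]), ix["clustered"], ix["unique"])
                    for ix in td["indexes"]
                ],
                foreign_keys=[
                    ForeignKeyDef(fk["column"], fk["target_table"], fk["target_column"])
                    for fk in td["foreign_keys"]
                ],
                key_column=td["key_column"],
                key_generated=td["key_generated"],
                ordinal_column=td["ordinal_column"],
                subject_column=td["subject_column"],
                group_tables=dict(td["group_tables"]),
                slot_children={k: tuple(v) for k, v in td["slot_children"].items()},
                parent_table=td["parent_table"],
                fk_column=td["fk_column"],
                group_path=td["group_path"],
                embedded_archetype_ids=list(td["embedded_archetype_ids"]),
            )
            schema.tables[t.name] = t
        for p in doc["provenance"]:
            schema.provenance[(p["archetype_id"], p["path"], p["field"])] = (
                p["table"], p["column"],
            )
        schema.archetype_tables = dict(doc["archetype_tables"])
        schema.version_registry = dict(doc["version_registry"])
        return schema


# -- naming (rule 8) -------------------------------------------------------

_SPLIT = re.compile(r"[ _\-]+")


def camel(text: str) -> str:
    return "".join(w[:1].upper() + w[1:] for w in _SPLIT.split(text) if w)


def shorten(name: str, limit: int) -> str:
    """Deterministic shortening: truncate and append a 4-hex-digit digest of
    the full name, so distinct long names stay distinct."""
    if len(name) <= limit:
        return name
    if limit < 6:
        raise MappingError(f"identifier limit {limit} too small")
    digest = hashlib.sha1(name.encode()).hexdigest()[:4]
    return f"{name[: limit - 5]}_{digest}"


def table_name_for(
    archetype: Archetype,
    config: MapperConfig,
    *,
    keep_version: bool = False,
) -> str:
    aid = archetype.archetype_id
    letter = config.prefix_letters.get(aid.rm_class, aid.rm_class[:1].upper())
    name = letter + camel(aid.concept_name)
    if keep_version:
        name += f"V{aid.version}"
    return shorten(name, config.name_limit)


def column_name_for(path_names: Sequence[str], suffix: Optional[str], config: MapperConfig) -> str:
    if config.column_mode == "path":
        base = names_to_path(list(path_names))
        name = f"{base}_{suffix}" if suffix else base
        return shorten(name, config.name_limit)
    segs = list(path_names)
    # the printed schema writes "id", not "id_id": a trailing segment equal to
    # the field suffix is not repeated
    if suffix and (not segs or segs[-1] != suffix):
        segs = segs + [suffix]
    return shorten("_".join(segs), config.name_limit)


def make_names(
    archetype: Archetype,
    node_path: Optional[str] = None,
    field_suffix: Optional[str] = None,
    limit: int = 64,
    config: Optional[MapperConfig] = None,
) -> str:
    """Render the identifier for a table (``node_path is None``), a
    collection/multi-item table (path of the group node), or a column
    (path + field suffix)."""
    config = replace(config or MapperConfig(), name_limit=limit)
    if node_path is None:
        return table_name_for(archetype, config)
    names = path_segments(coerce_path(node_path))
    if field_suffix is None:
        base = table_name_for(archetype, config)
        return shorten(base + camel(names[-1]), limit)
    return column_name_for(names, field_suffix, config)


# -- slot embedding (rule 5b) ----------------------------------------------


def _repath(node: DataNode, new_parent_path: str) -> DataNode:
    new_path = f"{new_parent_path}/[{node.name}]" if new_parent_path else f"[{node.name}]"
    if isinstance(node, CollectionItem):
        return replace(
            node,
            path=new_path,
            children=tuple(_repath(c, new_path) for c in node.children),
        )
    return replace(node, path=new_path)


def embed_slot(
    current: Archetype,
    slot: SlotItem,
    target: Archetype,
    suite: Optional[dict] = None,
    ontology_out: Optional[dict] = None,
    _stack: tuple = (),
) -> list:
    """Expand a single-occurrence slot: the target archetype's data items are
    re-pathed under the slot path.  Nested single-occurrence slots expand
    recursively; a cycle raises :class:`SlotCycleError`."""
    if slot.occurrence.is_many:
        raise MappingError(f"slot {slot.path} has upper bound *; embedding requires 1")
    if target.id_text in _stack or target.id_text == current.id_text:
        raise SlotCycleError(
            f"slot embedding cycle: {' -> '.join(_stack + (current.id_text, target.id_text))}"
        )
    out: list[DataNode] = []
    for node in target.root_nodes:
        repathed = _repath(node, slot.path)
        out.extend(
            _expand_node(
                repathed,
                target,
                node.path,
                suite,
                ontology_out,
                _stack + (current.id_text,),
            )
        )
    return out


def _expand_node(node, owner, owner_path, suite, ontology_out, stack):
    """Recursively expand ONE-slots inside a (re-pathed) node, carrying the
    owner archetype's ontology texts over to the new paths."""
    if ontology_out is not None and owner_path in owner.ontology:
        ontology_out[node.path] = dict(owner.ontology[owner_path])
    if isinstance(node, CollectionItem):
        new_children = []
        for child, ochild in zip(node.children, owner.node_at(owner_path).children):
            new_children.extend(
                _expand_node(child, owner, ochild.path, suite, ontology_out, stack)
            )
        return [replace(node, children=tuple(new_children))]
    if isinstance(node, SlotItem) and not node.occurrence.is_many:
        if suite is None or node.target_archetype_id not in suite:
            raise MappingError(f"unresolved slot target {node.target_archetype_id}")
        target = suite[node.target_archetype_id]
        if target.id_text in stack or target.id_text == owner.id_text:
            raise SlotCycleError(
                f"slot embedding cycle: {' -> '.join(stack + (owner.id_text, target.id_text))}"
            )
        # keep the slot node itself out; its children take its place under its path
        container_children: list[DataNode] = []
        for tnode in target.root_nodes:
            repathed = _repath(tnode, node.path)
            container_children.extend(
                _expand_node(repathed, target, tnode.path, suite, ontology_out,
                             stack + (owner.id_text,))
            )
        container = CollectionItem(
            name=node.name,
            path=node.path,
            kind="EMBEDDED_SLOT",
            children=tuple(container_children),
            occurrence=node.occurrence,
        )
        return [container]
    return [node]


def effective_tree(archetype: Archetype, suite: dict) -> tuple:
    """Node tree with every single-occurrence slot expanded in place.

    Returns ``(nodes, ontology, embedded_ids)``.
    """
    ontology = {p: dict(t) for p, t in archetype.ontology.items()}
    embedded: list[str] = []

    def collect_embedded(nodes):
        for n in nodes:
            if isinstance(n, SlotItem) and not n.occurrence.is_many:
                if n.target_archetype_id not in embedded:
                    embedded.append(n.target_archetype_id)
                    tgt = suite.get(n.target_archetype_id)
                    if tgt is not None:
                        collect_embedded(tgt.root_nodes)
            elif isinstance(n, CollectionItem):
                collect_embedded(n.children)

    collect_embedded(archetype.root_nodes)
    out: list[DataNode] = []
    for node in archetype.root_nodes:
        out.extend(_expand_node(node, archetype, node.path, suite, ontology, ()))
    return tuple(out), ontology, embedded


# -- the mapping proper ----------------------------------------------------


class _Builder:
    def __init__(self, archetypes, templates, eav_maps, config):
        self.suite = {}
        for a in archetypes:
            if a.id_text in self.suite:
                raise MappingError(f"duplicate archetype {a.id_text}")
            self.suite[a.id_text] = a
        self.templates = {}
        for t in templates:
            if t.archetype_id in self.templates:
                raise MappingError(
                    f"archetype {t.archetype_id} bound by two templates "
                    f"({self.templates[t.archetype_id].template_id}, {t.template_id}); "
                    "one template per archetype"
                )
            self.templates[t.archetype_id] = t
        self.eav_specialized = [m.specialized_archetype_id for m in eav_maps]
        self.config = config
        self.schema = RelationalSchema(config=config)

    # ..................................................................

    def tabled_archetypes(self) -> list:
        tabled: list[str] = []

        def add(aid):
            if aid not in tabled:
                if aid not in self.suite:
                    raise MappingError(f"unresolved archetype reference {aid}")
                tabled.append(aid)

        for aid in self.suite:
            if aid in self.templates:
                add(aid)
        for aid in self.eav_specialized:
            add(aid)
        # fixpoint over MANY-slot targets
        frontier = list(tabled)
        while frontier:
            aid = frontier.pop(0)
            nodes, _onto, _emb = effective_tree(self.suite[aid], self.suite)

            def scan(ns):
                for n in ns:
                    if isinstance(n, SlotItem) and n.occurrence.is_many:
                        if n.target_archetype_id not in tabled:
                            add(n.target_archetype_id)
                            frontier.append(n.target_archetype_id)
                    elif isinstance(n, CollectionItem):
                        scan(n.children)

            scan(nodes)
        # deterministic: input order
        return [aid for aid in self.suite if aid in tabled]

    # ..................................................................

    def build(self) -> RelationalSchema:
        for aid, tmpl in self.templates.items():
            if aid not in self.suite:
                raise MappingError(f"template {tmpl.template_id} references unknown {aid}")
            violations = validate_template(tmpl, self.suite[aid], self.suite)
            if violations:
                raise MappingError(
                    f"template {tmpl.template_id} invalid: " + "; ".join(violations)
                )
        order = self.tabled_archetypes()
        for aid in order:
            self._build_main_table(self.suite[aid])
        for aid in order:
            self._link_many_slots(self.suite[aid])
        self._check_invariants()
        return self.schema

    # ..................................................................

    def _unique_table_name(self, name: str) -> str:
        if name in self.schema.tables:
            raise MappingError(f"table name collision: {name}")
        return name

    def _add_column(self, table: TableDef, col: ColumnDef):
        if table.has_column(col.name):
            existing = table.column(col.name)
            raise MappingError(
                f"column name collision in {table.name}: {col.name} "
                f"({existing.provenance} vs {col.provenance})"
            )
        table.columns.append(col)

    def _record_provenance(self, aid, path, suffix, table, column):
        key = (aid, coerce_path(path), suffix)
        if key in self.schema.provenance:
            raise MappingError(f"provenance collision for {key}")
        self.schema.provenance[key] = (table, column)

    def _template_for(self, archetype: Archetype) -> Optional[Template]:
        return self.templates.get(archetype.id_text)

    def _effective_occurrence(self, archetype, node):
        tmpl = self._template_for(archetype)
        if tmpl:
            for p, occ in tmpl.optionality_overrides.items():
                if coerce_path(p) == node.path:
                    return occ
        return node.occurrence

    # ..................................................................

    def _build_main_table(self, archetype: Archetype):
        config = self.config
        nodes, ontology, embedded = effective_tree(archetype, self.suite)
        tmpl = self._template_for(archetype)
        name = self._unique_table_name(table_name_for(archetype, config))
        table = TableDef(
            name=name,
            origin=ARCHETYPE_MAIN,
            source_archetype_ids=[archetype.id_text],
            embedded_archetype_ids=list(embedded),
        )
        self.schema.tables[name] = table
        self.schema.archetype_tables[archetype.id_text] = name
        self.schema.version_registry[archetype.archetype_id.versionless] = name

        idi_path = None
        qdi_paths: list[str] = []
        suppressed: set = set()
        if tmpl:
            if tmpl.arm.identification_item:
                idi_path = coerce_path(tmpl.arm.identification_item)
            qdi_paths = [coerce_path(q) for q in tmpl.arm.query_items]
            suppressed = {
                (coerce_path(g), coerce_path(q))
                for g, q in tmpl.arm.suppressed_propagations
            }

        # rule 3: key column
        if idi_path is None:
            key_col = self._generated_key_name(nodes)
            table.key_column = key_col
            table.key_generated = True
            table.columns.append(
                ColumnDef(key_col, INTEGER, nullable=False, role=GENERATED_ID,
                          provenance=GENERATED)
            )
            table.indexes.append(IndexDef((key_col,), clustered=True, unique=True))

        deferred_children: list[tuple] = []
        self._emit_nodes(
            archetype, table, nodes, [], mandatory_so_far=True,
            idi_path=idi_path, deferred_children=deferred_children,
        )

        if idi_path is not None:
            tcol = self._column_for_path(archetype, table, idi_path)
            table.key_column = tcol
            table.key_generated = False
            col = table.column(tcol)
            col.nullable = False
            table.indexes.append(IndexDef((tcol,), clustered=True, unique=True))

        # rule 4: query data items
        qdi_cols = []
        for q in qdi_paths:
            qcol = self._column_for_path(archetype, table, q)
            if qcol not in table.indexed_columns():
                table.indexes.append(IndexDef((qcol,), clustered=False, unique=False))
            qdi_cols.append((q, qcol))

        table.subject_column = self._subject_column(archetype, table)

        # child tables (created after the parent's key/QDIs are final)
        for group_node, rel_nodes, origin in deferred_children:
            self._build_child_table(
                archetype, table, group_node, rel_nodes, origin, qdi_cols, suppressed
            )

    def _generated_key_name(self, nodes) -> str:
        taken = set()

        def walk(ns):
            for n in ns:
                taken.add(n.name)
                if isinstance(n, CollectionItem):
                    walk(n.children)

        walk(nodes)
        if "id" not in taken:
            return "id"
        return shorten("id_" + hashlib.sha1(b"generated id").hexdigest()[:4], 16)

    def _column_for_path(self, archetype, table, path) -> str:
        key = (archetype.id_text, path)
        for (aid, p, _s), (tname, col) in self.schema.provenance.items():
            if aid == archetype.id_text and p == path and tname == table.name:
                return col
        raise MappingError(
            f"{archetype.id_text}: constrained path {path!r} does not map to a "
            f"column of {table.name} (key {key})"
        )

    def _subject_column(self, archetype, table) -> Optional[str]:
        """The column carrying the patient/subject of an instance.

        Convention: a root basic item named "patient" is the subject
        reference; a demographic PERSON archetype's subject is its own
        identification item.
        """
        for (aid, path, _s), (tname, col) in self.schema.provenance.items():
            if aid == archetype.id_text and tname == table.name and path == "[patient]":
                return col
        if archetype.archetype_id.rm_class == "PERSON" and not table.key_generated:
            return table.key_column
        return None

    # ..................................................................

    def _emit_nodes(self, archetype, table, nodes, prefix_names, mandatory_so_far,
                    idi_path, deferred_children):
        for node in nodes:
            occ = self._effective_occurrence(archetype, node)
            if isinstance(node, BasicItem):
                if occ.is_many:
                    rel = replace(node, occurrence=replace(occ, upper="1"))
                    deferred_children.append((node, (rel,), MULTI_ITEM))
                    continue
                mandatory = mandatory_so_far and occ.mandatory
                for suffix, kind in resolve_field_columns(
                    node.type_name, dv_proportion_extended=self.config.dv_proportion_extended
                ):
                    cname = column_name_for(prefix_names + [node.name], suffix, self.config)
                    self._add_column(
                        table,
                        ColumnDef(
                            cname, kind,
                            nullable=not mandatory,
                            role=DATA,
                            provenance=("data", archetype.id_text, node.path, suffix),
                        ),
                    )
                    self._record_provenance(
                        archetype.id_text, node.path, suffix, table.name, cname
                    )
            elif isinstance(node, CollectionItem):
                if occ.is_many:
                    deferred_children.append((node, node.children, COLLECTION))
                else:
                    self._emit_nodes(
                        archetype, table, node.children,
                        prefix_names + [node.name],
                        mandatory_so_far and occ.mandatory,
                        idi_path, deferred_children,
                    )
            else:  # SlotItem with upper bound * (ONE-slots were expanded)
                if not occ.is_many:
                    raise MappingError(f"unresolved slot target {node.target_archetype_id}")
                table.slot_children[node.path] = (node.target_archetype_id, "")

    # ..................................................................

    def _build_child_table(self, archetype, parent, group_node, rel_nodes, origin,
                           qdi_cols, suppressed):
        config = self.config
        cname = shorten(parent.name + camel(group_node.name), config.name_limit)
        self._unique_table_name(cname)
        fk_col = shorten(f"{parent.name}_{parent.key_column}", config.name_limit)
        table = TableDef(
            name=cname,
            origin=origin,
            source_archetype_ids=[archetype.id_text],
            parent_table=parent.name,
            fk_column=fk_col,
            group_path=group_node.path,
            key_column="id",
            key_generated=True,
            ordinal_column="ordinal",
        )
        self.schema.tables[cname] = table
        parent.group_tables[group_node.path] = cname

        key_kind = INTEGER if parent.key_generated else parent.column(parent.key_column).storage_kind
        table.columns.append(
            ColumnDef("id", INTEGER, nullable=False, role=GENERATED_ID, provenance=GENERATED)
        )
        table.indexes.append(IndexDef(("id",), clustered=True, unique=True))
        table.columns.append(
            ColumnDef(fk_col, key_kind, nullable=False, role=FOREIGN_KEY,
                      provenance=("fk", archetype.id_text))
        )
        table.foreign_keys.append(ForeignKeyDef(fk_col, parent.name, parent.key_column))
        table.indexes.append(IndexDef((fk_col,), clustered=False, unique=False))
        table.columns.append(
            ColumnDef("ordinal", INTEGER, nullable=False, role=GENERATED_ID,
                      provenance=GENERATED)
        )

        deferred: list[tuple] = []
        self._emit_nodes(
            archetype, table, rel_nodes, [], mandatory_so_far=True,
            idi_path=None, deferred_children=deferred,
        )
        # nested multiple-occurrence groups hang off this table's generated key
        for nested_group, nested_nodes, nested_origin in deferred:
            self._build_child_table(
                archetype, table, nested_group, nested_nodes, nested_origin,
                qdi_cols, suppressed,
            )

        # rule 7: propagate unsuppressed query items of the host archetype
        for qpath, qcol in qdi_cols:
            if (group_node.path, qpath) in suppressed:
                continue
            pcol = shorten(f"{parent.name}_{qcol}", config.name_limit)
            src = parent.column(qcol)
            self._add_column(
                table,
                ColumnDef(pcol, src.storage_kind, nullable=True, role=PROPAGATED_QUERY,
                          provenance=("propagated", archetype.id_text) + src.provenance[2:]),
            )
            table.indexes.append(IndexDef((pcol,), clustered=False, unique=False))
        if parent.subject_column:
            for c in table.columns:
                if c.role == PROPAGATED_QUERY and c.provenance[2:] == \
                        parent.column(parent.subject_column).provenance[2:]:
                    table.subject_column = c.name
                    break

    # ..................................................................

    def _link_many_slots(self, archetype: Archetype):
        table = self.schema.table_for(archetype.id_text)
        tmpl = self._template_for(archetype)
        suppressed = set()
        qdi_paths = []
        if tmpl:
            qdi_paths = [coerce_path(q) for q in tmpl.arm.query_items]
            suppressed = {
                (coerce_path(g), coerce_path(q))
                for g, q in tmpl.arm.suppressed_propagations
            }
        for slot_path, (target_id, _) in list(table.slot_children.items()):
            target_table = self.schema.table_for(target_id)
            fk_col = shorten(f"{table.name}_{table.key_column}", self.config.name_limit)
            key_kind = (
                INTEGER if table.key_generated else table.column(table.key_column).storage_kind
            )
            self._add_column(
                target_table,
                ColumnDef(fk_col, key_kind, nullable=True, role=FOREIGN_KEY,
                          provenance=("fk", archetype.id_text)),
            )
            target_table.foreign_keys.append(
                ForeignKeyDef(fk_col, table.name, table.key_column)
            )
            target_table.indexes.append(IndexDef((fk_col,), clustered=False, unique=False))
            table.slot_children[slot_path] = (target_id, fk_col)
            for qpath in qdi_paths:
                if (slot_path, qpath) in suppressed:
                    continue
                qcol = self._column_for_path(archetype, table, qpath)
                src = table.column(qcol)
                pcol = shorten(f"{table.name}_{qcol}", self.config.name_limit)
                self._add_column(
                    target_table,
                    ColumnDef(pcol, src.storage_kind, nullable=True, role=PROPAGATED_QUERY,
                              provenance=("propagated", archetype.id_text) + src.provenance[2:]),
                )
                target_table.indexes.append(IndexDef((pcol,), clustered=False, unique=False))

    # ..................................................................

    def _check_invariants(self):
        for t in self.schema.tables.values():
            clustered = [ix for ix in t.indexes if ix.clustered]
            if len(clustered) != 1 or not clustered[0].unique:
                raise MappingError(f"table {t.name} must have exactly one unique clustered index")
            if clustered[0].columns != (t.key_column,):
                raise MappingError(f"clustered index of {t.name} is not on its key column")
        seen = {}
        for key, (tname, col) in self.schema.provenance.items():
            if (tname, col) in seen:
                raise MappingError(
                    f"provenance not bijective: {tname}.{col} claimed by {seen[(tname, col)]} "
                    f"and {key}"
                )
            seen[(tname, col)] = key


def map_schema(
    archetypes: Sequence[Archetype],
    templates: Sequence[Template] = (),
    eav_maps: Sequence = (),
    config: Optional[MapperConfig] = None,
) -> RelationalSchema:
    """Apply the mapping rules to produce a :class:`RelationalSchema`."""
    return _Builder(archetypes, templates, eav_maps, config or MapperConfig()).build()


# -- version handling (rule 1 / deployment strategies) ---------------------


@dataclass
class ConversionSpec:
    """Field conversions for MERGE_AND_CONVERT migrations.

    ``mappings`` is a list of (source column, target column, transform) with
    transform in {"identity", "text", "integer", "float"} (rename is identity
    under a different target name).
    """

    mappings: list


def merge_versions(
    schema: RelationalSchema,
    old: Archetype,
    new: Archetype,
    strategy: str = TABLE_PER_VERSION,
    conversion: Optional[ConversionSpec] = None,
):
    """Fold a new archetype version into the schema.

    Returns ``(schema, migration_plan_or_None)``.  REVISION extends the shared
    table in place (new-only leaves as nullable columns); SPECIALIZATION and
    NEW_VERSION+TABLE_PER_VERSION add a table; NEW_VERSION+MERGE_AND_CONVERT
    additionally returns a migration plan for the ddl emitter.
    """
    from .ddl import MigrationPlan  # local import: ddl depends on this module

    rel = classify_relationship(old, new)
    config = schema.config
    old_table = schema.table_for(old.id_text)

    if rel is SemanticRelationship.REVISION:
        _extend_table_for_revision(schema, old_table, old, new)
        return schema, None

    if rel is SemanticRelationship.SPECIALIZATION or strategy == TABLE_PER_VERSION:
        keep_version = rel is SemanticRelationship.NEW_VERSION
        # map the lone new archetype standalone, then graft its tables in
        sub = _Builder([new], [], [], config)
        sub.eav_specialized = [new.id_text]
        new_schema = sub.build()
        _graft(schema, new_schema, new, keep_version)
        return schema, None

    if strategy == MERGE_AND_CONVERT:
        if conversion is None:
            raise MigrationError(
                "MERGE_AND_CONVERT requires a field conversion specification"
            )
        sub = _Builder([new], [], [], config)
        sub.eav_specialized = [new.id_text]
        new_schema = sub.build()
        new_table = new_schema.table_for(new.id_text)
        final_name = old_table.name
        temp_name = shorten(final_name + "__migration", config.name_limit + 12)
        new_table.name = temp_name
        plan = MigrationPlan(
            source_table=final_name,
            target_table=temp_name,
            final_name=final_name,
            target_def=new_table,
            mappings=list(conversion.mappings),
        )
        # the schema model keeps the new definition under the final name
        registered = _clone_table(new_table, final_name)
        schema.tables[final_name] = registered
        schema.archetype_tables[new.id_text] = final_name
        schema.archetype_tables.pop(old.id_text, None)
        schema.version_registry[new.archetype_id.versionless] = final_name
        for key, (tname, col) in list(new_schema.provenance.items()):
            schema.provenance[key] = (final_name, col)
        for key in [k for k, v in list(schema.provenance.items()) if k[0] == old.id_text]:
            del schema.provenance[key]
        return schema, plan

    raise MigrationError(f"unknown version strategy {strategy!r}")


def _clone_table(t: TableDef, name: str) -> TableDef:
    import copy

    c = copy.deepcopy(t)
    c.name = name
    return c


def _extend_table_for_revision(schema, table, old, new):
    config = schema.config

    def emit(ns, prefix):
        for n in ns:
            if isinstance(n, BasicItem):
                if n.occurrence.is_many:
                    continue  # new multi-occurrence items need their own table
                for suffix, kind in resolve_field_columns(
                    n.type_name, dv_proportion_extended=config.dv_proportion_extended
                ):
                    key = (new.id_text, n.path, suffix)
                    old_key = (old.id_text, n.path, suffix)
                    if old_key in schema.provenance:
                        schema.provenance[key] = schema.provenance[old_key]
                        continue
                    cname = column_name_for(prefix + [n.name], suffix, config)
                    table.columns.append(
                        ColumnDef(cname, kind, nullable=True, role=DATA,
                                  provenance=("data", new.id_text, n.path, suffix))
                    )
                    schema.provenance[key] = (table.name, cname)
            elif isinstance(n, CollectionItem) and not n.occurrence.is_many:
                emit(n.children, prefix + [n.name])

    emit(new.root_nodes, [])
    if new.id_text not in table.source_archetype_ids:
        table.source_archetype_ids.append(new.id_text)
    schema.archetype_tables[new.id_text] = table.name


def _graft(schema, new_schema, new, keep_version):
    config = schema.config
    arch_table = new_schema.table_for(new.id_text)
    rename = {}
    if keep_version:
        final = table_name_for_archetype_with_version(new, config)
        rename[arch_table.name] = final
    for tname, t in new_schema.tables.items():
        final = rename.get(tname, tname)
        if final in schema.tables:
            raise MappingError(f"table name collision while grafting: {final}")
        t2 = _clone_table(t, final)
        if t2.parent_table in rename:
            t2.parent_table = rename[t2.parent_table]
        t2.foreign_keys = [
            replace(fk, target_table=rename.get(fk.target_table, fk.target_table))
            for fk in t2.foreign_keys
        ]
        t2.group_tables = {k: rename.get(v, v) for k, v in t2.group_tables.items()}
        schema.tables[final] = t2
    for key, (tname, col) in new_schema.provenance.items():
        schema.provenance[key] = (rename.get(tname, tname), col)
    schema.archetype_tables[new.id_text] = rename.get(arch_table.name, arch_table.name)
    if keep_version:
        schema.version_registry[new.id_text] = schema.archetype_tables[new.id_text]
    else:
        schema.version_registry[new.archetype_id.versionless] = (
            schema.archetype_tables[new.id_text]
        )


def table_name_for_archetype_with_version(archetype, config):
    return shorten(table_name_for(archetype, config) + f"V{archetype.archetype_id.version}",
                   config.name_limit)
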
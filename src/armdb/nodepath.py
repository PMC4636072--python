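"""Node+Path (EAV) reference backend.

One table per concept (per tabled archetype, named like the ARM table), each
holding ``<instance key, repetition ordinal, node path, serialized value>``
rows -- one row per populated leaf field, the full denormalized path stored
on every row.  That redundancy, and the full table scans queries over it
need, are the phenomenon this backend exists to reproduce; only the instance
key is indexed.

Values use a typed-prefix text encoding (``s:``/``i:``/``f:`` + canonical
rendering) so numeric query conditions can deserialize before comparing.
Rows whose path starts with ``~`` are bookkeeping, not leaf values: ``~key``
registers the instance, ``~rep`` registers a repetition with no populated
leaves, and ``~parent...`` links a multiple-occurrence slot child to its
parent instance.
"""

from __future__ import annotations

import sqlite3
from typing import Optional

from .archetype import CollectionItem, path_segments
from .errors import DuplicateKeyError, NotFoundError, QueryError, StoreError
from .instance import ArchetypeInstance, validate_instance
from .mapper import RelationalSchema, effective_tree
from .query import (
    INSTANCE,
    REPETITION,
    SUBJECT,
    QuerySpec,
    ResultSet,
    evaluate_condition,
    partition_conditions,
)
from .store import subject_leaf
from .types import resolve_field_columns


def serialize_value(v) -> str:
    if isinstance(v, bool):
        return f"i:{int(v)}"
    if isinstance(v, int):
        return f"i:{v}"
    if isinstance(v, float):
        return f"f:{v!r}"
    return f"s:{v}"


def deserialize_value(text: str):
    tag, _, body = text.partition(":")
    if tag == "i":
        return int(body)
    if tag == "f":
        return float(body)
    return body


def leaf_path_text(node_path: str, suffix: str) -> str:
    return f"{node_path}/value/{suffix}"


def split_leaf_path(text: str) -> tuple:
    head, sep, suffix = text.rpartition("/value/")
    if not sep:
        raise StoreError(f"malformed leaf path {text!r}")
    return head, suffix


class NodePathStore:
    """EAV persistence with the same instance and query contracts as the ARM
    backend.  The relational schema model is used as metadata only (concept
    table names, identification items, subject fields); the storage layout is
    the two-column node/value design plus instance key and ordinal."""

    def __init__(self, schema: RelationalSchema, suite, conn: sqlite3.Connection):
        self.schema = schema
        self.suite = suite if isinstance(suite, dict) else {a.id_text: a for a in suite}
        self.conn = conn
        self._eff_cache: dict = {}

    @classmethod
    def deploy(cls, schema, suite, conn) -> "NodePathStore":
        store = cls(schema, suite, conn)
        for aid, tname in schema.archetype_tables.items():
            conn.execute(
                f'CREATE TABLE IF NOT EXISTS "{tname}" ('
                "instance_key TEXT NOT NULL, "
                "ordinal INTEGER NOT NULL, "
                "node_path TEXT NOT NULL, "
                "value TEXT NOT NULL)"
            )
            conn.execute(
                f'CREATE INDEX IF NOT EXISTS "ix_np_{tname}_key" ON "{tname}" (instance_key)'
            )
        conn.commit()
        return store

    # -- helpers -----------------------------------------------------------

    def _table(self, archetype_id: str) -> str:
        try:
            return self.schema.archetype_tables[archetype_id]
        except KeyError:
            raise StoreError(f"no concept table for archetype {archetype_id}") from None

    def _effective(self, archetype_id: str):
        if archetype_id not in self._eff_cache:
            nodes, _onto, _emb = effective_tree(self.suite[archetype_id], self.suite)
            self._eff_cache[archetype_id] = nodes
        return self._eff_cache[archetype_id]

    def _key_of(self, instance: ArchetypeInstance):
        table = self.schema.table_for(instance.archetype_id)
        if table.key_generated:
            tname = self._table(instance.archetype_id)
            row = self.conn.execute(
                f'SELECT MAX(CAST(instance_key AS INTEGER)) FROM "{tname}" '
                "WHERE node_path = '~key'"
            ).fetchone()
            return (row[0] or 0) + 1
        prov = table.column(table.key_column).provenance
        leaf = instance.get(prov[2])
        key = leaf.get(prov[3]) if isinstance(leaf, dict) else None
        if key is None:
            raise StoreError(
                f"{instance.archetype_id}: missing identification value ({table.key_column})"
            )
        return key

    @staticmethod
    def _key_text(key) -> str:
        return str(key)

    def _typed_key(self, archetype_id: str, text: str):
        return int(text) if self.schema.table_for(archetype_id).key_generated else text

    # -- store -------------------------------------------------------------

    def store_instance(self, instance: ArchetypeInstance, commit: bool = True):
        validate_instance(instance, self.suite)
        key = self._store(instance, None)
        if commit:
            self.conn.commit()
        return key

    def _store(self, instance, parent_link):
        tname = self._table(instance.archetype_id)
        key = self._key_of(instance)
        ktext = self._key_text(key)
        exists = self.conn.execute(
            f'SELECT 1 FROM "{tname}" WHERE instance_key = ? AND node_path = ?',
            (ktext, "~key"),
        ).fetchone()
        if exists:
            raise DuplicateKeyError(f"{tname}: duplicate identification value {key!r}")

        rows = [(ktext, 0, "~key", serialize_value(key))]
        if parent_link is not None:
            slot_path, parent_key = parent_link
            rows.append((ktext, 0, f"~parent{slot_path}", serialize_value(parent_key)))
        children: list = []
        self._emit_rows(instance.archetype_id, self._effective(instance.archetype_id),
                        instance.values or {}, ktext, 0, False, rows, children)
        self.conn.executemany(
            f'INSERT INTO "{tname}" (instance_key, ordinal, node_path, value) '
            "VALUES (?, ?, ?, ?)",
            rows,
        )
        for slot_path, child_doc in children:
            child = ArchetypeInstance(child_doc["archetype_id"], child_doc.get("values", {}))
            validate_instance(child, self.suite)
            self._store(child, (slot_path, key))
        return key

    def _emit_rows(self, aid, nodes, values, ktext, ordinal, in_group, rows, children):
        from .archetype import BasicItem, SlotItem

        for node in nodes:
            v = (values or {}).get(node.name)
            if isinstance(node, SlotItem) and node.occurrence.is_many:
                for child_doc in v or []:
                    children.append((node.path, child_doc))
                continue
            if node.occurrence.is_many:
                if in_group:
                    raise StoreError(
                        "nested multiple-occurrence groups are not supported by "
                        "the node+path backend"
                    )
                for i, rep in enumerate(v or []):
                    before = len(rows)
                    if isinstance(node, BasicItem):
                        self._emit_leaf(node, rep, ktext, i, rows)
                    else:
                        self._emit_rows(aid, node.children, rep, ktext, i, True,
                                        rows, children)
                    if len(rows) == before:  # repetition with no populated leaves
                        rows.append((ktext, i, f"{node.path}/~rep", ""))
                continue
            if v is None:
                continue
            if isinstance(node, BasicItem):
                self._emit_leaf(node, v, ktext, ordinal, rows)
            elif isinstance(node, CollectionItem):
                self._emit_rows(aid, node.children, v, ktext, ordinal, in_group,
                                rows, children)

    @staticmethod
    def _emit_leaf(node, leaf, ktext, ordinal, rows):
        if not isinstance(leaf, dict):
            return
        for suffix, _kind in resolve_field_columns(node.type_name,
                                                   dv_proportion_extended=True):
            val = leaf.get(suffix)
            if val is None:
                continue
            rows.append((ktext, ordinal, leaf_path_text(node.path, suffix),
                         serialize_value(val)))

    # -- retrieve ----------------------------------------------------------

    def retrieve_instance(self, archetype_id: str, key) -> ArchetypeInstance:
        tname = self._table(archetype_id)
        ktext = self._key_text(key)
        raw = self.conn.execute(
            f'SELECT ordinal, node_path, value FROM "{tname}" WHERE instance_key = ?',
            (ktext,),
        ).fetchall()
        if not raw:
            raise NotFoundError(f"{archetype_id}: no instance with key {key!r}")

        nodes = self._effective(archetype_id)
        group_of, node_by_path = _index_tree(nodes)
        values: dict = {}
        rep_count: dict = {}
        for ordinal, path_text, _v in raw:
            if path_text.startswith("~"):
                continue
            node_path = path_text.split("/value/")[0].split("/~rep")[0]
            node = node_by_path.get(node_path)
            if node is not None and node.occurrence.is_many and \
                    isinstance(node, CollectionItem):
                gp = node_path  # a ~rep marker names the group itself
            else:
                gp = _nearest_group(node_path, group_of)
            if gp is not None:
                rep_count[gp] = max(rep_count.get(gp, 0), ordinal + 1)
        group_reps = {gp: [dict() for _ in range(n)] for gp, n in rep_count.items()}

        for ordinal, path_text, v in raw:
            if path_text.startswith("~") or path_text.endswith("/~rep"):
                continue
            node_path, suffix = split_leaf_path(path_text)
            gp = _nearest_group(node_path, group_of)
            if gp is None:
                _set_leaf(values, path_segments(node_path), suffix, deserialize_value(v))
            else:
                rel = path_segments(node_path)[len(path_segments(gp)):]
                target = group_reps[gp][ordinal]
                if not rel:  # multi-occurrence basic item
                    target[suffix] = deserialize_value(v)
                else:
                    _set_leaf(target, rel, suffix, deserialize_value(v))

        for gp, reps in group_reps.items():
            _set_node(values, path_segments(gp), reps)
        # every MANY group present in the tree round-trips as a list
        for p, node in node_by_path.items():
            from .archetype import SlotItem

            if node.occurrence.is_many and not isinstance(node, SlotItem) \
                    and p not in group_reps:
                _set_node(values, path_segments(p), [])

        # multiple-occurrence slot children
        for p, node in node_by_path.items():
            from .archetype import SlotItem

            if isinstance(node, SlotItem) and node.occurrence.is_many:
                target_table = self._table(node.target_archetype_id)
                child_rows = self.conn.execute(
                    f'SELECT instance_key FROM "{target_table}" '
                    "WHERE node_path = ? AND value = ?",
                    (f"~parent{p}", serialize_value(key)),
                ).fetchall()
                child_keys = sorted(
                    self._typed_key(node.target_archetype_id, r[0]) for r in child_rows
                )
                _set_node(
                    values, path_segments(p),
                    [
                        {"archetype_id": node.target_archetype_id,
                         "values": self.retrieve_instance(node.target_archetype_id, ck).values}
                        for ck in child_keys
                    ],
                )
        return ArchetypeInstance(archetype_id, values)

    # -- query -------------------------------------------------------------

    def _group_of_path_fn(self, archetype_id: str):
        group_of, node_by_path = _index_tree(self._effective(archetype_id))

        def lookup(norm_path: str):
            if norm_path not in node_by_path:
                raise QueryError(f"unresolvable path {norm_path!r} for {archetype_id}")
            return _nearest_group(norm_path, group_of)

        return lookup

    def _rows_for_path(self, tname, leaf_path):
        # the node path carries no index: this is the inevitable full scan
        return self.conn.execute(
            f'SELECT instance_key, ordinal, value FROM "{tname}" WHERE node_path = ?',
            (leaf_path,),
        ).fetchall()

    def _keys_matching(self, archetype_id: str, conditions) -> set:
        tname = self._table(archetype_id)
        main, partitions = partition_conditions(
            tuple(conditions), self._group_of_path_fn(archetype_id)
        )
        key_sets = []
        for cond in main:
            matched = set()
            for k, _o, v in self._rows_for_path(tname, leaf_path_text(cond.norm_path,
                                                                      cond.field)):
                if evaluate_condition(cond, deserialize_value(v)):
                    matched.add(k)
            key_sets.append(matched)
        for (_gp, _binding), conds in partitions.items():
            per_cond = []
            for cond in conds:
                vals = {}
                for k, o, v in self._rows_for_path(
                    tname, leaf_path_text(cond.norm_path, cond.field)
                ):
                    vals[(k, o)] = deserialize_value(v)
                per_cond.append({ko for ko, v in vals.items()
                                 if evaluate_condition(cond, v)})
            same_rep = set.intersection(*per_cond) if per_cond else set()
            key_sets.append({k for k, _o in same_rep})
        if not key_sets:
            rows = self.conn.execute(
                f'SELECT DISTINCT instance_key FROM "{tname}" WHERE node_path = ?',
                ("~key",),
            )
            return {r[0] for r in rows}
        out = key_sets[0]
        for s in key_sets[1:]:
            out &= s
        return out

    def run_query(self, spec: QuerySpec) -> ResultSet:
        if spec.group_unit == SUBJECT:
            subject_sets = []
            for term in spec.terms:
                keys = self._keys_matching(term.archetype_id, term.conditions)
                subject_sets.append(self._subjects_for(term.archetype_id, keys))
            out = subject_sets[0]
            for s in subject_sets[1:]:
                out &= s
            return ResultSet(SUBJECT, sorted(out))
        term = spec.terms[0]
        keys = {
            self._typed_key(term.archetype_id, k)
            for k in self._keys_matching(term.archetype_id, term.conditions)
        }
        if spec.projection is None:
            return ResultSet(INSTANCE, list(keys))
        return ResultSet(
            REPETITION,
            self._project_group(term.archetype_id, spec.projection, keys),
        )

    def _subjects_for(self, archetype_id: str, keys) -> set:
        path, suffix = subject_leaf(self.schema, archetype_id)
        tname = self._table(archetype_id)
        out = set()
        for k, _o, v in self._rows_for_path(tname, leaf_path_text(path, suffix)):
            if k in keys:
                out.add(deserialize_value(v))
        return out

    def _project_group(self, archetype_id: str, projection: str, keys) -> list:
        norm = projection if "[" in projection else \
            "/".join(f"[{s}]" for s in projection.split("/") if s)
        from .archetype import normalize_path

        norm = normalize_path(norm)
        tname = self._table(archetype_id)
        prefix = norm + "/"
        rows = self.conn.execute(
            f'SELECT instance_key, ordinal, node_path FROM "{tname}" '
            "WHERE node_path LIKE ? OR node_path LIKE ?",
            (norm + "/value/%", norm + "/%"),
        ).fetchall()
        out = set()
        for k, o, p in rows:
            if p.startswith(prefix) or p.startswith(norm + "/value/"):
                tk = self._typed_key(archetype_id, k)
                if tk in keys:
                    out.add((tk, o))
        return sorted(out)

    def all_keys(self, archetype_id: str) -> list:
        tname = self._table(archetype_id)
        rows = self.conn.execute(
            f'SELECT instance_key FROM "{tname}" WHERE node_path = ?', ("~key",)
        )
        return sorted(self._typed_key(archetype_id, r[0]) for r in rows)


def _index_tree(nodes):
    """(node path -> its repetition-group path or None, path -> node).

    A node's group is the path whose ordinal numbers its repetitions: the
    nearest enclosing MANY collection, or the node itself when it is a MANY
    basic item.  Main-level single-occurrence leaves map to None.
    """
    group_of: dict = {}
    node_by_path: dict = {}

    def rec(ns, group):
        for n in ns:
            node_by_path[n.path] = n
            if n.occurrence.is_many and not isinstance(n, CollectionItem) \
                    and not hasattr(n, "target_archetype_id"):
                group_of[n.path] = n.path  # MANY basic item: its own group
            else:
                group_of[n.path] = group
            if isinstance(n, CollectionItem):
                inner = n.path if n.occurrence.is_many else group
                rec(n.children, inner)

    rec(nodes, None)
    return group_of, node_by_path


def _nearest_group(path, group_of):
    return group_of.get(path)


def _set_leaf(values, names, suffix, v):
    cur = values
    for name in names[:-1]:
        cur = cur.setdefault(name, {})
    cur.setdefault(names[-1], {})[suffix] = v


def _set_node(values, names, node_value):
    cur = values
    for name in names[:-1]:
        cur = cur.setdefault(name, {})
    cur[names[-1]] = node_value
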
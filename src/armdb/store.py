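"""ARM backend: persist archetype instances into the generated relational
schema and answer queries.

Storage follows the mapping rules: single-occurrence leaves land in the main
row (embedded slots inline), every repetition of a multiple-occurrence group
becomes a child-table row carrying the foreign key, an ordinal, and copies
of the parent's propagated query items; multiple-occurrence slot children
are stored as instances of their own archetype with a foreign key back.

Query execution is stepwise by default, mirroring clinical practice with
the generated schema: one simple statement per condition group, key sets
intersected in the application, subjects resolved last.  A single-statement
join strategy is available for comparison.
"""

from __future__ import annotations

import sqlite3
from typing import Optional, Sequence

from .archetype import Archetype, normalize_path, path_segments
from .ddl import deploy
from .errors import DuplicateKeyError, NotFoundError, QueryError, StoreError
from .instance import ArchetypeInstance, validate_instance
from .mapper import (
    ARCHETYPE_MAIN,
    DATA,
    PROPAGATED_QUERY,
    RelationalSchema,
    TableDef,
)
from .query import (
    INSTANCE,
    REPETITION,
    SUBJECT,
    Condition,
    QuerySpec,
    ResultSet,
    condition_sql,
    partition_conditions,
)

_IN_CHUNK = 400


def _value_at(values: dict, names: Sequence[str]):
    cur = values
    for name in names:
        if not isinstance(cur, dict):
            return None
        cur = cur.get(name)
        if cur is None:
            return None
    return cur


def subject_leaf(schema: RelationalSchema, archetype_id: str) -> tuple:
    """(node path, field suffix) of the subject/patient field of an archetype."""
    table = schema.table_for(archetype_id)
    if not table.subject_column:
        raise QueryError(f"{archetype_id} has no subject/patient field in scope")
    prov = table.column(table.subject_column).provenance
    if prov[0] not in ("data",):
        raise QueryError(f"subject column of {table.name} is not an archetype field")
    return prov[2], prov[3]


class ArmStore:
    """Instance persistence and query over a deployed ARM database."""

    def __init__(self, schema: RelationalSchema, suite: dict, conn: sqlite3.Connection):
        self.schema = schema
        self.suite = suite if isinstance(suite, dict) else {a.id_text: a for a in suite}
        self.conn = conn
        conn.execute("PRAGMA foreign_keys = ON")

    @classmethod
    def deploy(cls, schema, suite, conn) -> "ArmStore":
        deploy(schema, conn)
        return cls(schema, suite, conn)

    # -- store -------------------------------------------------------------

    def store_instance(self, instance: ArchetypeInstance,
                       _extra_cols: Optional[dict] = None, commit: bool = True):
        validate_instance(instance, self.suite)
        key = self._store(instance, _extra_cols or {})
        if commit:
            self.conn.commit()
        return key

    def _store(self, instance, extra_cols):
        table = self.schema.table_for(instance.archetype_id)
        values = instance.values or {}
        row = dict(extra_cols)
        for col in table.columns:
            if col.provenance[0] != "data":
                continue
            _tag, aid, path, suffix = col.provenance
            if aid != instance.archetype_id:
                continue
            leaf = _value_at(values, path_segments(path))
            if isinstance(leaf, dict):
                row[col.name] = leaf.get(suffix)

        if table.key_generated:
            key = self._insert(table.name, row)
        else:
            key = row.get(table.key_column)
            if key is None:
                raise StoreError(
                    f"{instance.archetype_id}: missing identification value "
                    f"({table.key_column})"
                )
            self._insert(table.name, row)

        for group_path, child_name in table.group_tables.items():
            reps = _value_at(values, path_segments(group_path)) or []
            self._store_group(child_name, group_path, reps, key, instance)

        for slot_path, (target_id, fk_col) in table.slot_children.items():
            children = _value_at(values, path_segments(slot_path)) or []
            extra = {fk_col: key}
            for col in self.schema.table_for(target_id).columns:
                if col.role == PROPAGATED_QUERY and col.provenance[1] == instance.archetype_id:
                    leaf = _value_at(values, path_segments(col.provenance[2]))
                    if isinstance(leaf, dict):
                        extra[col.name] = leaf.get(col.provenance[3])
            for child_doc in children:
                child = ArchetypeInstance(child_doc["archetype_id"],
                                          child_doc.get("values", {}))
                self._store(child, dict(extra))
        return key

    def _store_group(self, child_name, group_path, reps, parent_key, instance):
        child = self.schema.tables[child_name]
        prefix_len = len(path_segments(group_path))
        for ordinal, rep in enumerate(reps):
            row = {child.fk_column: parent_key, child.ordinal_column: ordinal}
            for col in child.columns:
                tag = col.provenance[0]
                if tag == "data":
                    _t, _aid, path, suffix = col.provenance
                    rel = path_segments(path)[prefix_len:]
                    leaf = rep if not rel else _value_at(rep, rel)
                    if isinstance(leaf, dict):
                        row[col.name] = leaf.get(suffix)
                elif tag == "propagated":
                    leaf = _value_at(instance.values or {},
                                     path_segments(col.provenance[2]))
                    if isinstance(leaf, dict):
                        row[col.name] = leaf.get(col.provenance[3])
            child_key = self._insert(child_name, row)
            for nested_path, nested_name in child.group_tables.items():
                rel = path_segments(nested_path)[prefix_len:]
                nested_reps = _value_at(rep, rel) or []
                self._store_group(nested_name, nested_path, nested_reps,
                                  child_key, instance)

    def _insert(self, table_name, row):
        cols = [c for c, v in row.items() if v is not None]
        params = [row[c] for c in cols]
        sql = (
            f'INSERT INTO "{table_name}" ({", ".join(chr(34) + c + chr(34) for c in cols)}) '
            f'VALUES ({", ".join("?" * len(cols))})'
            if cols
            else f'INSERT INTO "{table_name}" DEFAULT VALUES'
        )
        try:
            cur = self.conn.execute(sql, params)
        except sqlite3.IntegrityError as exc:
            msg = str(exc)
            if "UNIQUE" in msg:
                raise DuplicateKeyError(f"{table_name}: {msg}") from None
            raise StoreError(f"{table_name}: {msg}") from None
        return cur.lastrowid

    # -- retrieve ----------------------------------------------------------

    def retrieve_instance(self, archetype_id: str, key) -> ArchetypeInstance:
        table = self.schema.table_for(archetype_id)
        cur = self.conn.execute(
            f'SELECT * FROM "{table.name}" WHERE "{table.key_column}" = ?', (key,)
        )
        row = cur.fetchone()
        if row is None:
            raise NotFoundError(f"{archetype_id}: no instance with key {key!r}")
        names = [d[0] for d in cur.description]
        record = dict(zip(names, row))
        values: dict = {}
        for col in table.columns:
            if col.provenance[0] != "data" or col.provenance[1] != archetype_id:
                continue
            v = record.get(col.name)
            if v is None:
                continue
            self._set_leaf(values, path_segments(col.provenance[2]), col.provenance[3], v)

        arch = self.suite[archetype_id]
        for group_path, child_name in table.group_tables.items():
            reps = self._load_group(child_name, group_path, key, archetype_id)
            self._set_node(values, path_segments(group_path), reps)

        for slot_path, (target_id, fk_col) in table.slot_children.items():
            target = self.schema.table_for(target_id)
            child_keys = [
                r[0]
                for r in self.conn.execute(
                    f'SELECT "{target.key_column}" FROM "{target.name}" '
                    f'WHERE "{fk_col}" = ? ORDER BY "{target.key_column}"',
                    (key,),
                )
            ]
            children = [
                {"archetype_id": target_id,
                 "values": self.retrieve_instance(target_id, ck).values}
                for ck in child_keys
            ]
            self._set_node(values, path_segments(slot_path), children)
        return ArchetypeInstance(archetype_id, values)

    def _load_group(self, child_name, group_path, parent_key, archetype_id):
        child = self.schema.tables[child_name]
        prefix_len = len(path_segments(group_path))
        cur = self.conn.execute(
            f'SELECT * FROM "{child_name}" WHERE "{child.fk_column}" = ? '
            f'ORDER BY "{child.ordinal_column}"',
            (parent_key,),
        )
        names = [d[0] for d in cur.description]
        reps = []
        for raw in cur.fetchall():
            record = dict(zip(names, raw))
            rep: dict = {}
            direct = None
            for col in child.columns:
                if col.provenance[0] != "data":
                    continue
                v = record.get(col.name)
                if v is None:
                    continue
                rel = path_segments(col.provenance[2])[prefix_len:]
                if not rel:  # multi-occurrence basic item: the row is the leaf
                    direct = direct or {}
                    direct[col.provenance[3]] = v
                else:
                    self._set_leaf(rep, rel, col.provenance[3], v)
            for nested_path, nested_name in child.group_tables.items():
                nested = self._load_group(
                    nested_name, nested_path, record[child.key_column], archetype_id
                )
                rel = path_segments(nested_path)[prefix_len:]
                self._set_node(rep, rel, nested)
            reps.append(direct if direct is not None else rep)
        return reps

    @staticmethod
    def _set_leaf(values, names, suffix, v):
        cur = values
        for name in names[:-1]:
            cur = cur.setdefault(name, {})
        cur.setdefault(names[-1], {})[suffix] = v

    @staticmethod
    def _set_node(values, names, node_value):
        cur = values
        for name in names[:-1]:
            cur = cur.setdefault(name, {})
        cur[names[-1]] = node_value

    # -- query -------------------------------------------------------------

    def _group_of_path(self, archetype_id: str):
        main = self.schema.table_for(archetype_id)

        def lookup(norm_path: str):
            for (aid, p, _s), (tname, _c) in self.schema.provenance.items():
                if aid == archetype_id and p == norm_path:
                    if tname == main.name:
                        return None
                    return self.schema.tables[tname].group_path
            raise QueryError(f"unresolvable path {norm_path!r} for {archetype_id}")

        return lookup

    def _condition_sql(self, archetype_id: str, cond: Condition) -> tuple:
        table_name, col = self.schema.resolve(archetype_id, cond.norm_path, cond.field)
        kind = self.schema.tables[table_name].column(col).storage_kind
        frag, param = condition_sql(cond, col, kind)
        return table_name, frag, param

    def _keys_matching(self, archetype_id: str, conditions) -> set:
        """Stepwise evaluation: one simple statement per condition group."""
        main = self.schema.table_for(archetype_id)
        term_main, partitions = partition_conditions(
            tuple(conditions), self._group_of_path(archetype_id)
        )
        key_sets = []
        if term_main:
            frags, params = [], []
            for cond in term_main:
                tname, frag, param = self._condition_sql(archetype_id, cond)
                if tname != main.name:
                    raise QueryError(f"condition {cond} does not resolve to the main table")
                frags.append(frag)
                params.append(param)
            rows = self.conn.execute(
                f'SELECT "{main.key_column}" FROM "{main.name}" WHERE ' + " AND ".join(frags),
                params,
            )
            key_sets.append({r[0] for r in rows})
        for (_gp, _binding), conds in partitions.items():
            frags, params, tables = [], [], set()
            for cond in conds:
                tname, frag, param = self._condition_sql(archetype_id, cond)
                tables.add(tname)
                frags.append(frag)
                params.append(param)
            if len(tables) != 1:
                raise QueryError("same-repetition conditions span different groups")
            child = self.schema.tables[tables.pop()]
            keys = {
                r[0]
                for r in self.conn.execute(
                    f'SELECT DISTINCT "{child.fk_column}" FROM "{child.name}" WHERE '
                    + " AND ".join(frags),
                    params,
                )
            }
            # climb nested child tables up to the main table's key
            while child.parent_table != main.name:
                parent = self.schema.tables[child.parent_table]
                keys = self._lift_keys(child.parent_table, parent, keys)
                child = parent
            key_sets.append(keys)
        if not key_sets:
            rows = self.conn.execute(f'SELECT "{main.key_column}" FROM "{main.name}"')
            return {r[0] for r in rows}
        out = key_sets[0]
        for s in key_sets[1:]:
            out &= s
        return out

    def _lift_keys(self, table_name, table, child_keys) -> set:
        out = set()
        ks = sorted(child_keys)
        for i in range(0, len(ks), _IN_CHUNK):
            chunk = ks[i : i + _IN_CHUNK]
            rows = self.conn.execute(
                f'SELECT DISTINCT "{table.fk_column}" FROM "{table_name}" '
                f'WHERE "{table.key_column}" IN ({", ".join("?" * len(chunk))})',
                chunk,
            )
            out.update(r[0] for r in rows)
        return out

    def _keys_matching_join(self, archetype_id: str, conditions) -> set:
        """Single-statement strategy: EXISTS subqueries instead of key-set
        intersection (kept for comparison with the stepwise default)."""
        main = self.schema.table_for(archetype_id)
        _tm, partitions = partition_conditions(
            tuple(conditions), self._group_of_path(archetype_id)
        )
        frags, params = [], []
        for cond in conditions:
            tname, frag, param = self._condition_sql(archetype_id, cond)
            if tname == main.name:
                frags.append(frag)
                params.append(param)
        for (_gp, _binding), conds in partitions.items():
            tname, _f, _p = self._condition_sql(archetype_id, conds[0])
            child = self.schema.tables[tname]
            if child.parent_table != main.name:
                return self._keys_matching(archetype_id, conditions)  # deep nesting
            sub_frags, sub_params = [], []
            for cond in conds:
                _t, frag, param = self._condition_sql(archetype_id, cond)
                sub_frags.append(frag)
                sub_params.append(param)
            # unqualified column names inside the subquery resolve to the
            # child table; only the correlation column needs qualifying
            frags.append(
                f'EXISTS (SELECT 1 FROM "{child.name}" c WHERE '
                f'c."{child.fk_column}" = m."{main.key_column}" AND '
                + " AND ".join(sub_frags)
                + ")"
            )
            params.extend(sub_params)
        where = (" WHERE " + " AND ".join(frags)) if frags else ""
        rows = self.conn.execute(
            f'SELECT m."{main.key_column}" FROM "{main.name}" m' + where, params
        )
        return {r[0] for r in rows}

    def run_query(self, spec: QuerySpec, strategy: str = "stepwise") -> ResultSet:
        matcher = self._keys_matching if strategy == "stepwise" else self._keys_matching_join
        if spec.group_unit == SUBJECT:
            subject_sets = []
            for term in spec.terms:
                keys = matcher(term.archetype_id, term.conditions)
                subject_sets.append(self._subjects_for(term.archetype_id, keys))
            out = subject_sets[0]
            for s in subject_sets[1:]:
                out &= s
            return ResultSet(SUBJECT, sorted(out))
        term = spec.terms[0]
        keys = matcher(term.archetype_id, term.conditions)
        if spec.projection is None:
            return ResultSet(INSTANCE, sorted(keys, key=lambda k: (isinstance(k, str), k)))
        return ResultSet(REPETITION, self._project_group(term.archetype_id, spec.projection, keys))

    def _subjects_for(self, archetype_id: str, keys) -> set:
        main = self.schema.table_for(archetype_id)
        if not main.subject_column:
            raise QueryError(f"{archetype_id} has no subject/patient field in scope")
        out = set()
        ks = sorted(keys, key=lambda k: (isinstance(k, str), str(k)))
        for i in range(0, len(ks), _IN_CHUNK):
            chunk = ks[i : i + _IN_CHUNK]
            rows = self.conn.execute(
                f'SELECT "{main.subject_column}" FROM "{main.name}" '
                f'WHERE "{main.key_column}" IN ({", ".join("?" * len(chunk))})',
                chunk,
            )
            out.update(r[0] for r in rows if r[0] is not None)
        return out

    def _project_group(self, archetype_id: str, projection: str, keys) -> list:
        main = self.schema.table_for(archetype_id)
        norm = normalize_path(projection if "[" in projection
                              else "/".join(f"[{s}]" for s in projection.split("/") if s))
        child_name = main.group_tables.get(norm)
        if child_name is None:
            raise QueryError(f"{archetype_id} has no multiple-occurrence group {projection!r}")
        child = self.schema.tables[child_name]
        rows = []
        ks = sorted(keys, key=lambda k: (isinstance(k, str), str(k)))
        for i in range(0, len(ks), _IN_CHUNK):
            chunk = ks[i : i + _IN_CHUNK]
            rows.extend(
                self.conn.execute(
                    f'SELECT "{child.fk_column}", "{child.ordinal_column}" '
                    f'FROM "{child_name}" '
                    f'WHERE "{child.fk_column}" IN ({", ".join("?" * len(chunk))})',
                    chunk,
                ).fetchall()
            )
        return [(r[0], r[1]) for r in rows]

    # -- utilities ---------------------------------------------------------

    def all_keys(self, archetype_id: str) -> list:
        main = self.schema.table_for(archetype_id)
        rows = self.conn.execute(
            f'SELECT "{main.key_column}" FROM "{main.name}" ORDER BY "{main.key_column}"'
        )
        return [r[0] for r in rows]

    def count(self, table_name: str) -> int:
        return self.conn.execute(f'SELECT COUNT(*) FROM "{table_name}"').fetchone()[0]


def load_instances(store, instances) -> list:
    """Bulk-load a stream of instances in one transaction; returns keys."""
    keys = [store.store_instance(inst, commit=False) for inst in instances]
    store.conn.commit()
    return keys
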
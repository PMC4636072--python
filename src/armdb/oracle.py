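"""Brute-force in-memory query evaluation over raw instance streams.

This evaluator answers the same query contract as the database backends by
walking every instance's value tree directly -- no SQL, no storage layout.
It exists as the reference semantics: backends are correct when they agree
with it on every query.  Keys are assigned exactly as the backends assign
them (the identification value, or 1-based insertion order for archetypes
with a generated key), so result sets are comparable verbatim.
"""

from __future__ import annotations

from .archetype import CollectionItem, SlotItem, normalize_path, path_segments
from .errors import QueryError
from .instance import ArchetypeInstance
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


class InMemoryOracle:
    def __init__(self, schema: RelationalSchema, suite):
        self.schema = schema
        self.suite = suite if isinstance(suite, dict) else {a.id_text: a for a in suite}
        #: archetype id -> list of (key, values)
        self.records: dict = {}
        self._counters: dict = {}
        self._eff: dict = {}

    def _effective(self, aid):
        if aid not in self._eff:
            nodes, _o, _e = effective_tree(self.suite[aid], self.suite)
            self._eff[aid] = nodes
        return self._eff[aid]

    def add(self, instance: ArchetypeInstance):
        """Register an instance (and, recursively, its slot children) with
        the key the backends would assign on the same stream."""
        aid = instance.archetype_id
        table = self.schema.table_for(aid)
        values = instance.values or {}
        if table.key_generated:
            self._counters[table.name] = self._counters.get(table.name, 0) + 1
            key = self._counters[table.name]
        else:
            prov = table.column(table.key_column).provenance
            leaf = _value_at(values, path_segments(prov[2]))
            key = leaf.get(prov[3]) if isinstance(leaf, dict) else None
            if key is None:
                raise QueryError(f"{aid}: instance lacks its identification value")
        self.records.setdefault(aid, []).append((key, values))
        for node in self._effective(aid):
            self._add_slot_children(node, values)
        return key

    def _add_slot_children(self, node, values):
        if isinstance(node, SlotItem) and node.occurrence.is_many:
            for child in (values or {}).get(node.name) or []:
                self.add(ArchetypeInstance(child["archetype_id"],
                                           child.get("values", {})))
        elif isinstance(node, CollectionItem) and not node.occurrence.is_many:
            self._add_slot_children_in(node.children, (values or {}).get(node.name))

    def _add_slot_children_in(self, nodes, values):
        for n in nodes:
            self._add_slot_children(n, values or {})

    def add_all(self, instances):
        for inst in instances:
            self.add(inst)

    # -- evaluation --------------------------------------------------------

    def _group_of_path_fn(self, aid):
        group_of: dict = {}

        def rec(ns, group):
            for n in ns:
                if n.occurrence.is_many and not isinstance(n, (CollectionItem, SlotItem)):
                    group_of[n.path] = n.path
                else:
                    group_of[n.path] = group
                if isinstance(n, CollectionItem):
                    rec(n.children, n.path if n.occurrence.is_many else group)

        rec(self._effective(aid), None)

        def lookup(norm_path):
            if norm_path not in group_of:
                raise QueryError(f"unresolvable path {norm_path!r} for {aid}")
            return group_of[norm_path]

        return lookup

    def _matches(self, aid, values, conditions, partitions_cache):
        main, partitions = partitions_cache
        for cond in main:
            leaf = _value_at(values, path_segments(cond.norm_path))
            v = leaf.get(cond.field) if isinstance(leaf, dict) else None
            if not evaluate_condition(cond, v):
                return False
        for (gp, _binding), conds in partitions.items():
            reps = _value_at(values, path_segments(gp))
            if not isinstance(reps, list):
                return False
            prefix = len(path_segments(gp))
            ok = False
            for rep in reps:
                all_ok = True
                for cond in conds:
                    rel = path_segments(cond.norm_path)[prefix:]
                    leaf = rep if not rel else _value_at(rep, rel)
                    v = leaf.get(cond.field) if isinstance(leaf, dict) else None
                    if not evaluate_condition(cond, v):
                        all_ok = False
                        break
                if all_ok:
                    ok = True
                    break
            if not ok:
                return False
        return True

    def run_query(self, spec: QuerySpec) -> ResultSet:
        if spec.group_unit == SUBJECT:
            subject_sets = []
            for term in spec.terms:
                keys = self._term_keys(term)
                subject_sets.append(self._subjects_for(term.archetype_id, keys))
            out = subject_sets[0]
            for s in subject_sets[1:]:
                out &= s
            return ResultSet(SUBJECT, sorted(out))
        term = spec.terms[0]
        keys = self._term_keys(term)
        if spec.projection is None:
            return ResultSet(INSTANCE, sorted(keys, key=str))
        return ResultSet(REPETITION,
                         self._project(term.archetype_id, spec.projection, keys))

    def _term_keys(self, term):
        parts = partition_conditions(term.conditions,
                                     self._group_of_path_fn(term.archetype_id))
        out = set()
        for key, values in self.records.get(term.archetype_id, []):
            if self._matches(term.archetype_id, values, term.conditions, parts):
                out.add(key)
        return out

    def _subjects_for(self, aid, keys):
        path, suffix = subject_leaf(self.schema, aid)
        out = set()
        for key, values in self.records.get(aid, []):
            if key in keys:
                leaf = _value_at(values, path_segments(path))
                v = leaf.get(suffix) if isinstance(leaf, dict) else None
                if v is not None:
                    out.add(v)
        return out

    def _project(self, aid, projection, keys):
        norm = normalize_path(projection if "[" in projection else
                              "/".join(f"[{s}]" for s in projection.split("/") if s))
        rows = []
        for key, values in self.records.get(aid, []):
            if key not in keys:
                continue
            reps = _value_at(values, path_segments(norm)) or []
            rows.extend((key, i) for i in range(len(reps)))
        return rows


def _value_at(values, names):
    cur = values
    for name in names:
        if not isinstance(cur, dict):
            return None
        cur = cur.get(name)
        if cur is None:
            return None
    return cur
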
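"""Archetype instances: value trees conforming to an archetype.

The value tree mirrors the archetype's node tree:

* a basic leaf carries a dict of field values keyed by field suffix
  (``{"magnitude": 7.4, "units": "mmol/L"}``);
* a single-occurrence collection or embedded slot carries a dict keyed by
  child name;
* a multiple-occurrence node carries an ordered list of such entries;
* a multiple-occurrence slot carries a list of nested instances
  (``{"archetype_id": ..., "values": ...}``).

Instances are interchanged as JSON documents (one per document; JSON-lines
for bulk loads).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .archetype import (
    Archetype,
    BasicItem,
    CollectionItem,
    SlotItem,
    path_segments,
)
from .errors import ValidationError
from .types import resolve_field_columns

_KIND_PY = {"NVARCHAR": str, "INTEGER": int, "FLOAT": (int, float)}


@dataclass
class ArchetypeInstance:
    archetype_id: str
    values: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"archetype_id": self.archetype_id, "values": self.values},
            sort_keys=True, ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArchetypeInstance":
        doc = json.loads(text)
        return cls(doc["archetype_id"], doc["values"])

    def get(self, path: str):
        """Value at a node path ("a/b" or "[a]/[b]"); None when absent.

        Descends through single-occurrence containers only; a multiple-
        occurrence node returns its repetition list.
        """
        names = _path_names(path)
        cur = self.values
        for i, name in enumerate(names):
            if not isinstance(cur, dict) or name not in cur:
                return None
            cur = cur[name]
            if isinstance(cur, list) and i < len(names) - 1:
                return None  # caller must iterate repetitions explicitly
        return cur


def _path_names(path: str) -> list:
    if "[" in path:
        return path_segments(path)
    return [p for p in path.split("/") if p]


def leaf_value(container: Optional[dict], suffix: str):
    if not isinstance(container, dict):
        return None
    return container.get(suffix)


# -- validation ------------------------------------------------------------


def _check_leaf(node: BasicItem, value, where: str):
    if not isinstance(value, dict):
        raise ValidationError(f"{where}: basic item value must be a field mapping")
    allowed = {s for s, _k in resolve_field_columns(node.type_name,
                                                    dv_proportion_extended=True)}
    for suffix, v in value.items():
        if suffix not in allowed:
            raise ValidationError(f"{where}: unknown field {suffix!r} for {node.type_name}")
        if v is None:
            continue
        kind = next(k for s, k in resolve_field_columns(node.type_name,
                                                        dv_proportion_extended=True)
                    if s == suffix)
        py = _KIND_PY[kind]
        if isinstance(v, bool):
            if kind != "INTEGER":
                raise ValidationError(f"{where}.{suffix}: boolean where {kind} expected")
        elif not isinstance(v, py):
            raise ValidationError(
                f"{where}.{suffix}: {type(v).__name__} where {kind} expected"
            )


def validate_instance(instance: ArchetypeInstance, suite: dict) -> None:
    """Raise :class:`ValidationError` unless the value tree conforms to the
    archetype's node structure, occurrences and field kinds."""
    arch = suite.get(instance.archetype_id)
    if arch is None:
        raise ValidationError(f"unknown archetype {instance.archetype_id}")
    _validate_nodes(arch.root_nodes, instance.values, suite, instance.archetype_id)


def _validate_nodes(nodes, values, suite, where):
    if values is None:
        values = {}
    if not isinstance(values, dict):
        raise ValidationError(f"{where}: expected a mapping of node values")
    known = {n.name for n in nodes}
    for name in values:
        if name not in known:
            raise ValidationError(f"{where}: unknown node {name!r}")
    for node in nodes:
        v = values.get(node.name)
        occ = node.occurrence
        present = v is not None and v != [] and v != {}
        if occ.mandatory and not present:
            raise ValidationError(f"{where}: missing mandatory item {node.path}")
        if v is None:
            continue
        if occ.is_many:
            if not isinstance(v, list):
                raise ValidationError(
                    f"{where}: {node.path} has occurrence {occ.render()}; "
                    "a repetition list is required"
                )
            reps = v
        else:
            if isinstance(v, list):
                raise ValidationError(
                    f"{where}: {node.path} is single-occurrence but has "
                    f"{len(v)} repetitions"
                )
            reps = [v]
        for rep in reps:
            if isinstance(node, BasicItem):
                _check_leaf(node, rep, f"{where}:{node.path}")
            elif isinstance(node, CollectionItem):
                _validate_nodes(node.children, rep, suite, f"{where}:{node.path}")
            elif isinstance(node, SlotItem):
                if occ.is_many:
                    if not isinstance(rep, dict) or "archetype_id" not in rep:
                        raise ValidationError(
                            f"{where}: {node.path} repetitions must be nested instances"
                        )
                    if rep["archetype_id"] != node.target_archetype_id:
                        raise ValidationError(
                            f"{where}: slot {node.path} expects "
                            f"{node.target_archetype_id}, got {rep['archetype_id']}"
                        )
                    child = ArchetypeInstance(rep["archetype_id"], rep.get("values", {}))
                    validate_instance(child, suite)
                else:
                    target = suite.get(node.target_archetype_id)
                    if target is None:
                        raise ValidationError(
                            f"{where}: unresolved slot target {node.target_archetype_id}"
                        )
                    _validate_nodes(target.root_nodes, rep, suite,
                                    f"{where}:{node.path}")


# -- normalization ---------------------------------------------------------


def normalize_instance(instance: ArchetypeInstance, suite: dict) -> ArchetypeInstance:
    """Canonical form for structural comparison.

    Absent optional composites and all-None leaves are dropped; absent
    multiple-occurrence nodes become empty lists; multiple-occurrence slot
    children are ordered by their serialized form (stored order of
    collection repetitions is significant and preserved).
    """
    arch = suite[instance.archetype_id]
    values = _normalize_nodes(arch.root_nodes, instance.values or {}, suite)
    return ArchetypeInstance(instance.archetype_id, values)


def _normalize_nodes(nodes, values, suite):
    out = {}
    for node in nodes:
        v = (values or {}).get(node.name)
        if node.occurrence.is_many:
            reps = v or []
            if isinstance(node, SlotItem):
                norm = [
                    {
                        "archetype_id": r["archetype_id"],
                        "values": _normalize_nodes(
                            suite[r["archetype_id"]].root_nodes, r.get("values", {}), suite
                        ),
                    }
                    for r in reps
                ]
                norm.sort(key=lambda d: json.dumps(d, sort_keys=True))
            else:
                norm = [_normalize_entry(node, r, suite) for r in reps]
            out[node.name] = norm
        else:
            if v is None:
                continue
            entry = _normalize_entry(node, v, suite)
            if entry:
                out[node.name] = entry
    return out


def _normalize_entry(node, v, suite):
    if isinstance(node, BasicItem):
        return {k: val for k, val in (v or {}).items() if val is not None}
    if isinstance(node, CollectionItem):
        return _normalize_nodes(node.children, v or {}, suite)
    # single-occurrence slot: normalize against the target archetype
    target = suite[node.target_archetype_id]
    return _normalize_nodes(target.root_nodes, v or {}, suite)


def instances_equal(a: ArchetypeInstance, b: ArchetypeInstance, suite: dict) -> bool:
    na, nb = normalize_instance(a, suite), normalize_instance(b, suite)
    return na.archetype_id == nb.archetype_id and na.values == nb.values


# -- randomized conformant instances (for property tests) ------------------

_WORDS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta")


def _random_field(kind: str, rng):
    if kind == "NVARCHAR":
        return "-".join(rng.choice(len(_WORDS), size=2).astype(str)) + "-" + \
            _WORDS[int(rng.integers(len(_WORDS)))]
    if kind == "INTEGER":
        return int(rng.integers(-1000, 1000))
    return float(round(float(rng.normal(50, 25)), 6))


def random_instance(
    archetype: Archetype,
    suite: dict,
    rng,
    key_sequence=None,
    _depth: int = 0,
) -> ArchetypeInstance:
    """A random instance conforming to ``archetype``.

    ``key_sequence`` is an iterator yielding unique identification strings;
    when provided, every DvIdentifier/DvText leaf named ``id`` or ending in
    ``Identifier`` draws from it, keeping unique-key constraints satisfiable.
    """

    def fill_nodes(nodes, depth):
        values = {}
        for node in nodes:
            occ = node.occurrence
            if occ.is_many:
                n = int(rng.integers(occ.lower, 4))
                reps = [fill_entry(node, depth) for _ in range(n)]
                values[node.name] = reps
            else:
                present = occ.mandatory or rng.random() < 0.7
                if present:
                    values[node.name] = fill_entry(node, depth)
        return values

    def fill_entry(node, depth):
        if isinstance(node, BasicItem):
            out = {}
            for suffix, kind in resolve_field_columns(node.type_name):
                if key_sequence is not None and kind == "NVARCHAR" and (
                    node.name == "id" or node.name.lower().endswith("identifier")
                ):
                    out[suffix] = next(key_sequence)
                else:
                    out[suffix] = _random_field(kind, rng)
            return out
        if isinstance(node, CollectionItem):
            return fill_nodes(node.children, depth)
        target = suite[node.target_archetype_id]
        if node.occurrence.is_many:
            child = random_instance(target, suite, rng, key_sequence, depth + 1)
            return {"archetype_id": child.archetype_id, "values": child.values}
        return fill_nodes(target.root_nodes, depth)

    return ArchetypeInstance(archetype.id_text, fill_nodes(archetype.root_nodes, _depth))
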
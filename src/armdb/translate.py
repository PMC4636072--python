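"""Generalized/specialized query and instance translation.

Concrete lab panels (blood gases, full blood count, ...) are specialized
archetypes whose analytes map, via EAV mapping files, onto the generalized
name/value/unit archetype.  Data stored one way can then be queried the
other way:

* a specialized condition ``PaO2.magnitude >= 129`` becomes, over the
  generalized storage, the same-repetition pair
  ``name field = "PaO2" AND value field >= 129``;
* a generalized condition pair ``(name = X, value >= v)`` becomes, over the
  specialized storage, a condition on the analyte whose display name is X in
  whichever panel defines it -- the reverse direction unions the
  per-specialized-archetype result sets.
"""

from __future__ import annotations

from typing import Sequence

from .archetype import Archetype, normalize_path
from .errors import TranslationError
from .instance import ArchetypeInstance
from .query import SUBJECT, Condition, QuerySpec, QueryTerm, query
from .template import EavMapping, _split_eav_path


def _display_of(arch: Archetype, norm_path: str, lang: str = "en") -> str:
    texts = arch.ontology.get(norm_path, {})
    return texts.get(lang) or next(iter(texts.values()), norm_path)


def _target_leaf(generalized: Archetype, target_path: str) -> tuple:
    """Resolve a Table-4 target path to (node path, field suffix) in the
    generalized archetype."""
    item_path, field_name = _split_eav_path(target_path)
    display = item_path.split("/")[-1][1:-1] if item_path else ""
    node = generalized.find_by_display(display)
    return node.path, (field_name or "value")


def _field_entry_for(mapping: EavMapping, display: str, suffix: str):
    wanted = normalize_path(f"[{display}]") + f"/value/{suffix}"
    for fe in mapping.field_entries:
        if fe.source_field_path == wanted:
            return fe
    return None


def _name_entry_for(mapping: EavMapping, display: str):
    wanted = normalize_path(f"[{display}]")
    for ne in mapping.name_entries:
        if ne.source_item_path == wanted:
            return ne
    return None


def translate_specialized_query(
    spec: QuerySpec,
    mapping: EavMapping,
    specialized: Archetype,
    generalized: Archetype,
) -> QuerySpec:
    """Rewrite a query on a specialized archetype to run over generalized
    storage.  Each specialized condition becomes a same-repetition pair
    (name equality + translated field condition); distinct analytes bind
    distinct repetitions of the same instance."""
    terms = []
    for term in spec.terms:
        if term.archetype_id != specialized.id_text:
            terms.append(term)
            continue
        out: list[Condition] = []
        for i, cond in enumerate(term.conditions):
            display = _display_of(specialized, cond.norm_path)
            ne = _name_entry_for(mapping, display)
            fe = _field_entry_for(mapping, display, cond.field)
            if ne is None or fe is None:
                raise TranslationError(
                    f"condition path {cond.path!r}/{cond.field} is not covered "
                    f"by the mapping onto {mapping.generalized_archetype_id}"
                )
            name_path, name_suffix = _target_leaf(generalized, ne.target_name_path)
            val_path, val_suffix = _target_leaf(generalized, fe.target_field_path)
            label = f"analyte:{display}:{i}"
            out.append(Condition(name_path, name_suffix, "=", display, group=label))
            out.append(Condition(val_path, val_suffix, cond.op, cond.value, group=label))
        terms.append(QueryTerm(generalized.id_text, tuple(out)))
    return QuerySpec(tuple(terms), spec.group_unit, spec.projection)


def translate_generalized_query(
    spec: QuerySpec,
    mappings: Sequence[EavMapping],
    suite: dict,
) -> list:
    """Rewrite a generalized-archetype query into per-specialized queries
    (one per mapping that covers its analytes); the caller unions the
    result sets.

    The generalized query is expected in the translated shape: repetition-
    labelled (name = X, value cmp v) pairs.  Labels group each pair.
    """
    out = []
    term = spec.terms[0]
    generalized_id = term.archetype_id
    # regroup conditions by label: (name literal, value conditions)
    groups: dict = {}
    for cond in term.conditions:
        if cond.group is None:
            raise TranslationError(
                "generalized conditions must be repetition-labelled (name, value) pairs"
            )
        groups.setdefault(cond.group, []).append(cond)
    analytes = []
    for label, conds in groups.items():
        name = next((c.value for c in conds if c.op == "=" and isinstance(c.value, str)),
                    None)
        value_conds = [c for c in conds if not (c.op == "=" and c.value == name)]
        if name is None:
            raise TranslationError(f"repetition group {label!r} carries no name equality")
        analytes.append((str(name), value_conds))

    generalized = suite[generalized_id]
    for mapping in mappings:
        if mapping.generalized_archetype_id != generalized_id:
            continue
        specialized = suite[mapping.specialized_archetype_id]
        conds: list[Condition] = []
        covered = True
        for name, value_conds in analytes:
            ne = _name_entry_for(mapping, name)
            if ne is None:
                covered = False
                break
            try:
                node = specialized.find_by_display(name)
            except KeyError:
                covered = False
                break
            for vc in value_conds:
                # reverse the field entry: which specialized field feeds this target?
                suffix = None
                for fe in mapping.field_entries:
                    src_item, src_field = _split_eav_path(fe.source_field_path)
                    if src_item != normalize_path(f"[{name}]"):
                        continue
                    t_path, t_suffix = _target_leaf(generalized, fe.target_field_path)
                    if t_path == vc.norm_path and t_suffix == vc.field:
                        suffix = src_field
                        break
                if suffix is None:
                    covered = False
                    break
                conds.append(Condition(node.path, suffix, vc.op, vc.value))
            if not covered:
                break
        if covered and len(analytes) > 0:
            out.append(query(specialized.id_text, conds, group_unit=spec.group_unit))
    if not out:
        raise TranslationError("no mapping covers the query's analytes")
    return out


def translate_specialized_instance(
    instance: ArchetypeInstance,
    mapping: EavMapping,
    specialized: Archetype,
    generalized: Archetype,
    extra_values: dict = None,
) -> ArchetypeInstance:
    """Re-express a specialized instance as a generalized one: every mapped
    analyte leaf becomes one repetition of the generalized group carrying
    (name, value, unit); unmapped structural items copy over by node name."""
    values = dict(instance.values or {})
    group_path = None
    reps = []
    for ne in mapping.name_entries:
        display = ne.source_item_path.split("/")[-1][1:-1]
        try:
            node = specialized.find_by_display(display, ne.language_set)
        except KeyError:
            continue
        leaf = instance.get(node.path)
        if not isinstance(leaf, dict):
            continue
        name_path, name_suffix = _target_leaf(generalized, ne.target_name_path)
        group_path = group_path or name_path.rsplit("/", 1)[0]
        rep: dict = {}
        _set(rep, name_path, name_suffix, display, group_path)
        for fe in mapping.field_entries:
            src_item, src_field = _split_eav_path(fe.source_field_path)
            if src_item != ne.source_item_path:
                continue
            v = leaf.get(src_field)
            if v is None:
                continue
            t_path, t_suffix = _target_leaf(generalized, fe.target_field_path)
            _set(rep, t_path, t_suffix, v if isinstance(v, str) else _render(v),
                 group_path)
        values.pop(node.name, None)
        reps.append(rep)
    if group_path is not None:
        seg = group_path.split("/")[-1][1:-1]
        values[seg] = reps
    # drop leaves the generalized archetype does not define
    gen_names = {n.name for n in generalized.root_nodes}
    values = {k: v for k, v in values.items() if k in gen_names}
    # mandatory generalized items the panel lacks (e.g. the identification
    # item) are supplied by the caller
    values.update(extra_values or {})
    return ArchetypeInstance(generalized.id_text, values)


def _render(v) -> str:
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(v)


def _set(rep: dict, node_path: str, suffix: str, value, group_path: str):
    from .archetype import path_segments

    rel = path_segments(node_path)[len(path_segments(group_path)):]
    cur = rep
    for name in rel[:-1]:
        cur = cur.setdefault(name, {})
    cur.setdefault(rel[-1], {})[suffix] = value
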
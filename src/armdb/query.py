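"""Backend-neutral query specifications and result sets.

A query is a conjunction of conditions over the fields of one or more
archetypes.  Conditions on leaves inside a multiple-occurrence group hold
when *some* repetition satisfies them; conditions sharing an explicit
``group`` label must be satisfied by the *same* repetition (the form
generalized/specialized translation produces: "the repetition whose name
field says PaO2 is the one whose value field is compared").  A query over
several archetypes intersects per-archetype subject sets and therefore
requires SUBJECT grouping.

Comparators are limited to ``=``, ``>=``, ``<=`` and ``LIKE`` -- the forms
clinical retrieval and patient-searching workloads use.  Numeric comparison
against text-typed storage follows SQL CAST semantics (leading numeric
prefix, else 0), so the relational backends, the node+path backend and the
in-memory reference evaluator agree on edge cases.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .archetype import normalize_path
from .errors import QueryError

INSTANCE = "INSTANCE"
SUBJECT = "SUBJECT"
REPETITION = "REPETITION"

COMPARATORS = ("=", ">=", "<=", "LIKE")


@dataclass(frozen=True)
class Condition:
    path: str  # node path, "a/b" or "[a]/[b]"
    field: str  # field suffix, e.g. "magnitude"
    op: str
    value: object
    #: conditions sharing a label bind to the same repetition
    group: Optional[str] = None

    def __post_init__(self):
        if self.op not in COMPARATORS:
            raise QueryError(f"unsupported comparator {self.op!r}")

    @property
    def norm_path(self) -> str:
        p = self.path
        if "[" not in p:
            p = "/".join(f"[{s}]" for s in p.split("/") if s)
        return normalize_path(p)


@dataclass(frozen=True)
class QueryTerm:
    archetype_id: str
    conditions: tuple = ()


@dataclass(frozen=True)
class QuerySpec:
    terms: tuple
    group_unit: str = INSTANCE
    #: None projects instance keys; a multiple-occurrence group path projects
    #: its repetitions as (instance key, ordinal) rows
    projection: Optional[str] = None

    def __post_init__(self):
        if not self.terms:
            raise QueryError("query needs at least one term")
        if len(self.terms) > 1 and self.group_unit != SUBJECT:
            raise QueryError("multi-archetype queries require SUBJECT grouping")
        if self.projection is not None and self.group_unit == SUBJECT:
            raise QueryError("repetition projection and SUBJECT grouping are exclusive")

    @property
    def target(self) -> str:
        return self.terms[0].archetype_id


def query(
    archetype_id: str,
    conditions: Sequence[Condition] = (),
    group_unit: str = INSTANCE,
    projection: Optional[str] = None,
) -> QuerySpec:
    """Single-archetype query (the common case)."""
    return QuerySpec(
        terms=(QueryTerm(archetype_id, tuple(conditions)),),
        group_unit=group_unit,
        projection=projection,
    )


def intersect_subjects(specs: Sequence[QuerySpec]) -> QuerySpec:
    """Combine single-archetype SUBJECT queries into one multi-archetype
    query (patients satisfying every per-archetype criterion)."""
    terms = []
    for s in specs:
        terms.extend(s.terms)
    return QuerySpec(terms=tuple(terms), group_unit=SUBJECT)


@dataclass
class ResultSet:
    unit: str  # INSTANCE | SUBJECT | REPETITION
    rows: list = field(default_factory=list)  # sorted, duplicate-free

    def __post_init__(self):
        self.rows = sorted(set(self.rows), key=_row_key)

    def keys(self) -> list:
        return list(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def digest(self) -> str:
        payload = json.dumps({"unit": self.unit, "rows": [list(r) if isinstance(r, tuple)
                                                          else r for r in self.rows]},
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _row_key(row):
    if isinstance(row, tuple):
        return tuple(_row_key(x) for x in row)
    # keys may mix generated integers and identification strings across tables
    return (0, row) if isinstance(row, (int, float)) else (1, str(row))


# -- comparator semantics shared by every execution route ------------------

_NUM_PREFIX = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?")


def sql_cast_real(value) -> float:
    """SQL CAST(x AS REAL): longest numeric prefix of the text, else 0."""
    if value is None:
        return 0.0
    if isinstance(value, (int, float)):
        return float(value)
    m = _NUM_PREFIX.match(str(value).strip())
    return float(m.group(0)) if m else 0.0


def _as_number(text):
    try:
        return float(str(text).strip())
    except (TypeError, ValueError):
        return None


def like_match(pattern: str, value) -> bool:
    """SQL LIKE with % and _, ASCII case-insensitive (sqlite default)."""
    if value is None:
        return False
    rx = re.escape(str(pattern)).replace("%", ".*").replace("_", ".")
    return re.fullmatch(rx, str(value), flags=re.IGNORECASE | re.DOTALL) is not None


def evaluate_condition(cond: Condition, value) -> bool:
    """Evaluate one condition against a leaf value (reference semantics,
    matching the SQL comparator including CAST and cross-type ordering)."""
    if cond.op == "LIKE":
        return like_match(cond.value, value)
    if value is None:
        return False
    if isinstance(cond.value, (int, float)) and not isinstance(cond.value, bool):
        v = sql_cast_real(value)
        w = float(cond.value)
    elif isinstance(value, (int, float)) and not isinstance(value, bool):
        # text literal against numeric storage: SQL applies the column's
        # numeric affinity when the text parses as a number, otherwise
        # orders every number before every text value
        lit = _as_number(cond.value)
        if lit is None:
            return cond.op == "<="
        v, w = float(value), lit
    else:
        v, w = str(value), str(cond.value)
    if cond.op == "=":
        return v == w
    if cond.op == ">=":
        return v >= w
    return v <= w


def condition_sql(cond: Condition, column: str, column_kind: str) -> tuple:
    """(sql_fragment, parameter) realizing the condition on a column."""
    numeric_literal = isinstance(cond.value, (int, float)) and not isinstance(cond.value, bool)
    col = f'"{column}"'
    if cond.op == "LIKE":
        return f"{col} LIKE ?", str(cond.value)
    if numeric_literal and column_kind == "NVARCHAR":
        col = f"CAST({col} AS REAL)"
    if numeric_literal:
        return f"{col} {cond.op} ?", float(cond.value)
    return f"{col} {cond.op} ?", str(cond.value)


def partition_conditions(conditions: Sequence[Condition], group_of_path) -> tuple:
    """Split conditions into main-level conjuncts and repetition partitions.

    ``group_of_path`` maps a normalized node path to the path of its nearest
    multiple-occurrence ancestor (None for main-level leaves).  Returns
    ``(main_conditions, partitions)`` where partitions is a dict
    ``(group_path, binding) -> [conditions]``; unlabeled conditions get a
    private binding (independent EXISTS), labeled ones share it.
    """
    main = []
    partitions: dict = {}
    label_groups: dict = {}
    for i, cond in enumerate(conditions):
        gp = group_of_path(cond.norm_path)
        if gp is None:
            if cond.group is not None:
                raise QueryError(
                    f"condition on {cond.path!r} carries repetition label "
                    f"{cond.group!r} but is not inside a multiple-occurrence group"
                )
            main.append(cond)
        else:
            binding = cond.group if cond.group is not None else f"__c{i}"
            if cond.group is not None:
                prev = label_groups.setdefault(cond.group, gp)
                if prev != gp:
                    raise QueryError(
                        f"repetition label {cond.group!r} spans groups {prev} and {gp}"
                    )
            partitions.setdefault((gp, binding), []).append(cond)
    return main, partitions


__all__ = [
    "Condition", "QueryTerm", "QuerySpec", "ResultSet",
    "query", "intersect_subjects",
    "INSTANCE", "SUBJECT", "REPETITION",
    "sql_cast_real", "like_match", "evaluate_condition", "condition_sql",
    "partition_conditions",
]
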
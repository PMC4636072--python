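"""Render a relational schema model to executable DDL, and run migrations.

Two dialects are supported.  ``sqlite`` is the default, embedded engine:
clustered indexes do not exist there, so the clustered unique key is emulated
-- a generated INTEGER key becomes ``INTEGER PRIMARY KEY`` (the rowid, which
does determine physical order), a declared identification item becomes a
UNIQUE index, and the emulation is recorded in an output comment.
``generic-ansi`` emits portable ANSI DDL with the CLUSTERED keyword carried
in comments.

DDL emission is deterministic: the same schema and dialect produce
byte-identical output.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from typing import Optional

from .errors import MigrationError
from .mapper import GENERATED_ID, RelationalSchema, TableDef

SQLITE = "sqlite"
GENERIC_ANSI = "generic-ansi"

_SQLITE_TYPES = {"NVARCHAR": "TEXT", "INTEGER": "INTEGER", "FLOAT": "REAL"}
_ANSI_TYPES = {"NVARCHAR": "NVARCHAR(4000)", "INTEGER": "INTEGER", "FLOAT": "FLOAT"}


@dataclass(frozen=True)
class Dialect:
    name: str
    type_map: dict
    #: how tables without native clustered indexes realize physical key order
    clustered_emulation: Optional[str] = None

    @classmethod
    def sqlite(cls) -> "Dialect":
        return cls(SQLITE, dict(_SQLITE_TYPES), "rowid-primary-key")

    @classmethod
    def generic_ansi(cls) -> "Dialect":
        return cls(GENERIC_ANSI, dict(_ANSI_TYPES), None)

    @classmethod
    def by_name(cls, name: str) -> "Dialect":
        if name == SQLITE:
            return cls.sqlite()
        if name == GENERIC_ANSI:
            return cls.generic_ansi()
        raise ValueError(f"unknown dialect {name!r}")


def _render_table(table: TableDef, dialect: Dialect) -> list:
    lines = [f"-- table {table.name} ({table.origin}; from {', '.join(table.source_archetype_ids)})"]
    col_lines = []
    sqlite_rowid_key = (
        dialect.name == SQLITE and table.key_generated
    )
    for col in table.columns:
        sql_type = dialect.type_map[col.storage_kind]
        parts = [f'"{col.name}"', sql_type]
        if sqlite_rowid_key and col.name == table.key_column and col.role == GENERATED_ID:
            # rowid alias: physically orders the table, emulating the
            # clustered unique index on the generated key
            parts.append("PRIMARY KEY")
        elif not col.nullable:
            parts.append("NOT NULL")
        col_lines.append("  " + " ".join(parts))
    for fk in table.foreign_keys:
        col_lines.append(
            f'  FOREIGN KEY ("{fk.column}") REFERENCES "{fk.target_table}" ("{fk.target_column}")'
        )
    lines.append(f'CREATE TABLE "{table.name}" (')
    lines.append(",\n".join(col_lines))
    lines.append(");")
    for ix in table.indexes:
        cols = ", ".join(f'"{c}"' for c in ix.columns)
        ix_name = f"ix_{table.name}_" + "_".join(ix.columns)
        if ix.clustered:
            if dialect.name == SQLITE:
                if sqlite_rowid_key:
                    lines.append(
                        f"-- clustered unique index on {table.name}({cols}) emulated by the "
                        "INTEGER PRIMARY KEY rowid above"
                    )
                    continue
                lines.append(
                    f"-- clustered index emulated as UNIQUE (sqlite orders rows by rowid)"
                )
                lines.append(f'CREATE UNIQUE INDEX "{ix_name}" ON "{table.name}" ({cols});')
            else:
                lines.append(f"-- CLUSTERED")
                unique = "UNIQUE " if ix.unique else ""
                lines.append(f'CREATE {unique}INDEX "{ix_name}" ON "{table.name}" ({cols});')
        else:
            unique = "UNIQUE " if ix.unique else ""
            lines.append(f'CREATE {unique}INDEX "{ix_name}" ON "{table.name}" ({cols});')
    return lines


def emit_ddl(schema: RelationalSchema, dialect: Optional[Dialect] = None) -> str:
    """Render the schema as DDL text (empty schema -> empty text)."""
    dialect = dialect or Dialect.sqlite()
    if not schema.tables:
        return ""
    for t in schema.tables.values():
        for col in t.columns:
            if len(col.name) > 128:
                raise MigrationError(
                    f"identifier {col.name!r} exceeds dialect limits; "
                    "name shortening should have prevented this"
                )
    chunks = [f"-- dialect: {dialect.name}"]
    for name in schema.tables:  # insertion order: deterministic
        chunks.extend(_render_table(schema.tables[name], dialect))
        chunks.append("")
    return "\n".join(chunks).rstrip() + "\n"


def deploy(schema: RelationalSchema, conn: sqlite3.Connection) -> None:
    conn.executescript(emit_ddl(schema, Dialect.sqlite()))
    conn.execute("PRAGMA foreign_keys = ON")


def emit_revision_alter(table: TableDef, new_columns, dialect: Optional[Dialect] = None) -> str:
    """ALTER statements adding the nullable columns a compatible revision
    introduced; existing rows keep their data."""
    dialect = dialect or Dialect.sqlite()
    lines = []
    for col in new_columns:
        sql_type = dialect.type_map[col.storage_kind]
        lines.append(f'ALTER TABLE "{table.name}" ADD COLUMN "{col.name}" {sql_type};')
    return "\n".join(lines) + ("\n" if lines else "")


# -- introspection (the execute-and-introspect oracle hook) ----------------


def introspect(conn: sqlite3.Connection) -> dict:
    """Read tables, columns, indexes and foreign keys back from a live sqlite
    database, in the golden-schema dict shape (structural parts only)."""
    out = {}
    rows = conn.execute(
        "SELECT name FROM sqlite_master WHERE type='table' AND name NOT LIKE 'sqlite_%'"
        " ORDER BY name"
    ).fetchall()
    for (tname,) in rows:
        cols = []
        pk_cols = []
        for cid, name, ctype, notnull, _dflt, pk in conn.execute(
            f'PRAGMA table_info("{tname}")'
        ):
            cols.append({"name": name, "type": ctype, "nullable": not notnull and not pk})
            if pk:
                pk_cols.append(name)
        indexes = []
        for _seq, ixname, unique, origin, _partial in conn.execute(
            f'PRAGMA index_list("{tname}")'
        ):
            if origin == "pk":
                continue
            ixcols = [r[2] for r in conn.execute(f'PRAGMA index_info("{ixname}")')]
            indexes.append({"columns": ixcols, "unique": bool(unique)})
        fks = [
            {"column": row[3], "target_table": row[2], "target_column": row[4]}
            for row in conn.execute(f'PRAGMA foreign_key_list("{tname}")')
        ]
        out[tname] = {
            "columns": cols,
            "primary_key": pk_cols,
            "indexes": sorted(indexes, key=lambda d: d["columns"]),
            "foreign_keys": sorted(fks, key=lambda d: d["column"]),
        }
    return out


def schema_matches_database(schema: RelationalSchema, conn: sqlite3.Connection) -> list:
    """Compare the schema model with a live database; returns mismatch
    messages (empty list = structurally equal)."""
    live = introspect(conn)
    problems = []
    dialect = Dialect.sqlite()
    for name, table in schema.tables.items():
        if name not in live:
            problems.append(f"table {name} missing from database")
            continue
        lt = live[name]
        model_cols = [
            (c.name, dialect.type_map[c.storage_kind], c.nullable) for c in table.columns
        ]
        live_cols = [(c["name"], c["type"], c["nullable"]) for c in lt["columns"]]
        if model_cols != live_cols:
            problems.append(f"{name}: columns differ: {model_cols} != {live_cols}")
        want_ix = set()
        for ix in table.indexes:
            if ix.clustered and table.key_generated:
                continue  # emulated by INTEGER PRIMARY KEY
            want_ix.add((tuple(ix.columns), ix.unique))
        have_ix = {(tuple(i["columns"]), i["unique"]) for i in lt["indexes"]}
        if want_ix != have_ix:
            problems.append(f"{name}: indexes differ: {sorted(want_ix)} != {sorted(have_ix)}")
        if table.key_generated and lt["primary_key"] != [table.key_column]:
            problems.append(f"{name}: generated key {table.key_column} is not the primary key")
        want_fk = {(fk.column, fk.target_table, fk.target_column) for fk in table.foreign_keys}
        have_fk = {(f["column"], f["target_table"], f["target_column"])
                   for f in lt["foreign_keys"]}
        if want_fk != have_fk:
            problems.append(f"{name}: foreign keys differ")
    for name in live:
        if name not in schema.tables:
            problems.append(f"unexpected table {name} in database")
    return problems


# -- migrations ------------------------------------------------------------


@dataclass
class MigrationPlan:
    """Create the new version's table, copy with field mapping, verify row
    counts, drop the old table, take over its name."""

    source_table: str
    target_table: str
    final_name: str
    target_def: TableDef
    #: (source column, target column, transform); transform in
    #: {"identity", "text", "integer", "float"}
    mappings: list = field(default_factory=list)


_TRANSFORM_SQL = {
    "identity": '"{src}"',
    "text": 'CAST("{src}" AS TEXT)',
    "integer": 'CAST("{src}" AS INTEGER)',
    "float": 'CAST("{src}" AS REAL)',
}


def apply_migration(plan: MigrationPlan, conn: sqlite3.Connection) -> dict:
    """Execute a migration plan; returns a per-step report.

    Aborts before copying when a not-null target data column lacks a
    mapping; aborts with rollback on a row-count mismatch.
    """
    report = {"steps": [], "ok": False}

    exists = conn.execute(
        "SELECT 1 FROM sqlite_master WHERE type='table' AND name=?", (plan.source_table,)
    ).fetchone()
    if not exists:
        raise MigrationError(f"source table {plan.source_table} does not exist")

    mapped_targets = {dst for _src, dst, _t in plan.mappings}
    for col in plan.target_def.columns:
        if col.role == GENERATED_ID:
            continue
        if not col.nullable and col.name not in mapped_targets:
            raise MigrationError(
                f"no conversion mapping for not-null column {col.name} "
                f"of {plan.final_name}; aborting before copy"
            )
    for name, _t in ((t, None) for _s, t, _x in plan.mappings):
        if not plan.target_def.has_column(name):
            raise MigrationError(f"mapping targets unknown column {name}")

    schema_like = RelationalSchema()
    schema_like.tables[plan.target_def.name] = plan.target_def
    try:
        conn.execute("BEGIN")
        conn.executescript(emit_ddl(schema_like, Dialect.sqlite()))
        report["steps"].append(("create", plan.target_table, "ok"))

        select_parts = []
        target_cols = []
        for src, dst, transform in plan.mappings:
            try:
                tpl = _TRANSFORM_SQL[transform]
            except KeyError:
                raise MigrationError(f"unknown transform {transform!r}") from None
            select_parts.append(tpl.format(src=src))
            target_cols.append(f'"{dst}"')
        if target_cols:
            conn.execute(
                f'INSERT INTO "{plan.target_table}" ({", ".join(target_cols)}) '
                f'SELECT {", ".join(select_parts)} FROM "{plan.source_table}"'
            )
        report["steps"].append(("copy", len(plan.mappings), "ok"))

        n_src = conn.execute(f'SELECT COUNT(*) FROM "{plan.source_table}"').fetchone()[0]
        n_dst = conn.execute(f'SELECT COUNT(*) FROM "{plan.target_table}"').fetchone()[0]
        if target_cols and n_src != n_dst:
            raise MigrationError(f"row count mismatch: {n_src} source vs {n_dst} target")
        if not target_cols and n_src != 0 and n_dst != n_src:
            # degenerate plan over a non-empty source cannot preserve rows
            raise MigrationError(f"empty mapping cannot copy {n_src} rows")
        report["steps"].append(("verify_counts", n_src, "ok"))

        conn.execute(f'DROP TABLE "{plan.source_table}"')
        report["steps"].append(("drop", plan.source_table, "ok"))
        if plan.target_table != plan.final_name:
            conn.execute(
                f'ALTER TABLE "{plan.target_table}" RENAME TO "{plan.final_name}"'
            )
            report["steps"].append(("rename", plan.final_name, "ok"))
        conn.commit()
    except Exception:
        conn.rollback()
        raise
    report["ok"] = True
    report["rows"] = n_src
    return report
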
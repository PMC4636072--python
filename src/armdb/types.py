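"""Archetype basic data types and their relational field mappings.

Each basic data type (``DvQuantity``, ``DvCodedText``, ...) is a small record
of named fields.  A field either has a primitive storage kind -- ``text``,
``integer`` or ``float``, rendered as NVARCHAR / INTEGER / FLOAT -- or refers
to another basic type, in which case its columns are obtained by expanding the
reference chain and joining the field names with underscores
(``definingCode`` -> ``definingCode_code``).  Reference chains are acyclic and
short by construction; :func:`resolve_field_columns` expands them eagerly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

# relational storage kinds
NVARCHAR = "NVARCHAR"
INTEGER = "INTEGER"
FLOAT = "FLOAT"

_PRIMITIVE_TO_SQL = {"text": NVARCHAR, "integer": INTEGER, "float": FLOAT}


@dataclass(frozen=True)
class FieldSpec:
    """One field of a basic data type.

    ``kind`` is ``"text"``/``"integer"``/``"float"`` for primitive fields or
    the name of another basic type for reference fields.
    """

    name: str
    kind: str

    @property
    def is_reference(self) -> bool:
        return self.kind not in _PRIMITIVE_TO_SQL


@dataclass(frozen=True)
class BasicTypeSpec:
    type_name: str
    field_specs: tuple[FieldSpec, ...]


def _t(name: str, *fields: tuple[str, str]) -> BasicTypeSpec:
    return BasicTypeSpec(name, tuple(FieldSpec(n, k) for n, k in fields))


#: The closed registry of archetype basic data types.  String fields map to
#: NVARCHAR, Boolean and Integer fields to INTEGER, Double fields to FLOAT,
#: URI fields are stored as their text rendering.  Fields naming another
#: basic type are reference fields and expand through that type's fields.
BASIC_TYPES: dict[str, BasicTypeSpec] = {
    t.type_name: t
    for t in (
        _t("CodePhrase", ("code", "text")),
        _t("DvBoolean", ("value", "integer")),
        _t("DvCodedText", ("definingCode", "CodePhrase")),
        _t("DvCount", ("magnitude", "integer")),
        _t("DvDateTime", ("value", "text")),
        _t("DvEHRURI", ("value", "text")),
        _t("DvIdentifier", ("id", "text")),
        _t("DvMultimedia", ("uri", "DvURI")),
        _t("DvProportion", ("precision", "integer")),
        _t("DvQuantity", ("magnitude", "float"), ("units", "text")),
        _t("DvText", ("value", "text")),
        _t("DvURI", ("value", "text")),
        _t("GenericID", ("value", "text"), ("name", "text")),
        _t("Link", ("target", "DvEHRURI")),
    )
}

#: Extra columns for DvProportion when the extended profile is enabled.  The
#: canonical mapping stores only the precision; ratio storage of the numerator
#: and denominator is opt-in (see MapperConfig.dv_proportion_extended).
DV_PROPORTION_EXTENSION = (("numerator", FLOAT), ("denominator", FLOAT))


def get_basic_type(name: str) -> BasicTypeSpec:
    try:
        return BASIC_TYPES[name]
    except KeyError:
        raise KeyError(f"unknown basic type name: {name!r}") from None


def resolve_field_columns(
    basic_type: Union[BasicTypeSpec, str],
    *,
    dv_proportion_extended: bool = False,
) -> list[tuple[str, str]]:
    """Expand a basic type into an ordered ``(column_suffix, storage_kind)`` list.

    Reference fields are expanded recursively; suffixes concatenate the field
    names along the chain with an underscore.  Storage kinds are drawn from
    {NVARCHAR, INTEGER, FLOAT}.
    """
    if isinstance(basic_type, str):
        basic_type = get_basic_type(basic_type)
    out: list[tuple[str, str]] = []
    for field in basic_type.field_specs:
        if field.is_reference:
            for suffix, kind in resolve_field_columns(get_basic_type(field.kind)):
                out.append((f"{field.name}_{suffix}", kind))
        else:
            out.append((field.name, _PRIMITIVE_TO_SQL[field.kind]))
    if dv_proportion_extended and basic_type.type_name == "DvProportion":
        out.extend(DV_PROPORTION_EXTENSION)
    return out


def leaf_fields(type_name: str) -> list[str]:
    """Column suffixes of a basic type (identity of the instance leaf fields)."""
    return [suffix for suffix, _ in resolve_field_columns(type_name)]


def storage_kind_of(type_name: str, suffix: str) -> str:
    for s, kind in resolve_field_columns(type_name, dv_proportion_extended=True):
        if s == suffix:
            return kind
    raise KeyError(f"{type_name} has no field {suffix!r}")
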
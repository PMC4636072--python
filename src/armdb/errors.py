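"""Exception hierarchy for the ARM toolkit."""


class ArmError(Exception):
    """Base class for all errors raised by this package."""


class DialectSyntaxError(ArmError):
    """A definition document is not well-formed.

    Carries a human-readable position when the underlying parser provides one.
    """

    def __init__(self, message, position=None):
        self.position = position
        if position is not None:
            message = f"{message} (at {position})"
        super().__init__(message)


class ValidationError(ArmError):
    """A model object violates a structural invariant."""


class LineageError(ArmError):
    """Two archetypes do not share a concept lineage."""


class MappingError(ArmError):
    """Schema mapping failed (unresolved slot, name collision, ...)."""


class SlotCycleError(MappingError):
    """Single-occurrence slot embedding would recurse forever."""


class StoreError(ArmError):
    """Instance persistence or retrieval failed."""


class NotFoundError(StoreError):
    """No instance with the requested key exists."""


class DuplicateKeyError(StoreError):
    """An identification value is already present (unique index violation)."""


class QueryError(ArmError):
    """A query specification cannot be resolved against the schema."""


class TranslationError(QueryError):
    """A condition path is not covered by the generalized/specialized mapping."""


class MigrationError(ArmError):
    """A schema migration plan is invalid or failed mid-flight."""
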
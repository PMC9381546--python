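"""Exception hierarchy for the metaqtl package."""


class MetaQtlError(Exception):
    """Base class for all package errors."""


class FormatError(MetaQtlError):
    """A tabular input is malformed (missing column, empty table, ...)."""


class DomainError(MetaQtlError, ValueError):
    """An argument violates a documented domain restriction."""


class InsufficientAnchorsError(MetaQtlError):
    """Fewer than two usable shared markers between two maps."""


class DegenerateIntervalError(MetaQtlError):
    """A zero-length source anchor interval; no expansion ratio exists."""


class UnusableRecordError(MetaQtlError):
    """A QTL record lacks every field combination needed for projection."""

    def __init__(self, qtl_id: str, missing: list[str]):
        self.qtl_id = qtl_id
        self.missing = list(missing)
        super().__init__(
            f"QTL {qtl_id!r} cannot be projected; missing fields: {', '.join(missing)}"
        )


class LookupFailure(MetaQtlError, KeyError):
    """A marker or locus was not found in a lookup table."""


class ConsistencyError(MetaQtlError):
    """Two inputs that must agree (e.g. chromosomes of flanking markers) do not."""


class AlignmentError(MetaQtlError):
    """Sequences passed as an alignment have unequal lengths."""


class DegenerateTableError(MetaQtlError):
    """A contingency table has an empty row or column margin."""
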
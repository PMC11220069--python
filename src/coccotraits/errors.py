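"""Exception hierarchy for the coccotraits pipeline."""


class CoccotraitsError(Exception):
    """Base class for all package errors."""


class DomainError(CoccotraitsError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class ValidationError(CoccotraitsError, ValueError):
    """A registry row, record or config failed validation."""


class UnresolvedTaxonError(CoccotraitsError, LookupError):
    """A taxon key matched no registry entry at any fallback level."""


class IncompleteRecordError(CoccotraitsError, ValueError):
    """A record lacks a required measurement and no fallback applies."""

    def __init__(self, record_id: str, field: str, message: str | None = None):
        self.record_id = record_id
        self.field = field
        super().__init__(
            message or f"record {record_id!r}: missing required field {field!r}"
        )


class RuleNotApplicableError(CoccotraitsError, ValueError):
    """A taxon-specific correction rule was invoked for a taxon without it."""


class ConfigurationError(CoccotraitsError, ValueError):
    """Registry parameters are internally inconsistent for a requested rule."""
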
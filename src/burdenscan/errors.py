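"""Exception hierarchy for burdenscan."""


class BurdenscanError(Exception):
    """Base class for all burdenscan errors."""


class SchemaError(BurdenscanError):
    """A table is missing required columns or has malformed values."""


class IntegrityError(BurdenscanError):
    """Cross-table references are inconsistent (dangling sample/variant ids)."""


class ValidationError(BurdenscanError):
    """A field value violates a documented invariant."""


class ConfigError(BurdenscanError):
    """An analysis or QC configuration is invalid."""
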
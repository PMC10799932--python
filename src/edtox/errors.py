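"""Exception hierarchy."""


class EdtoxError(Exception):
    """Base class for package errors."""


class SchemaError(EdtoxError):
    """A CSV file is missing a required column or has a malformed value."""


class IntegrityError(EdtoxError):
    """Referential/uniqueness violation in an extract (e.g. duplicate visit_id)."""


class ConfigError(EdtoxError):
    """A configuration artifact (lexicon, code spec, panel) is invalid."""


class ParameterError(EdtoxError):
    """Generator parameters are out of range or mutually infeasible."""
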
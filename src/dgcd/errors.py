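"""Exception hierarchy shared across the package.

The CLI maps these to exit codes: ConfigError -> 2, ValidationError and
SchemaError -> 3, InsufficientDataError -> 4.
"""


class DGCDError(Exception):
    """Base class for all package errors."""


class ValidationError(DGCDError, ValueError):
    """Input data violates an invariant (bipartiteness, duplicates, empty matrix ...)."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns or is otherwise malformed."""


class ConfigError(DGCDError, ValueError):
    """A pipeline or generator configuration is invalid."""


class GenerationError(DGCDError, RuntimeError):
    """The synthetic generator exhausted its retry budget for an infeasible config."""


class InsufficientDataError(DGCDError, RuntimeError):
    """Fewer networks survive filtering than the analysis requires."""
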
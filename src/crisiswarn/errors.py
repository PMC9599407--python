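"""Exception hierarchy shared across the package."""


class CrisisWarnError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CrisisWarnError):
    """A run-configuration value (matrix shape, decay factor, ...) is invalid."""


class ValidationError(CrisisWarnError):
    """An input record or vector violates a documented invariant."""


class SchemaError(CrisisWarnError):
    """A structured input file is missing a required field."""
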
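"""Exception hierarchy shared across the package."""


class AllomemError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AllomemError, ValueError):
    """An argument violates an operation's preconditions."""


class DegenerateGeometryError(AllomemError, ValueError):
    """A geometric solve is undefined (e.g. all points coincident)."""


class GenerationError(AllomemError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class ConfigError(AllomemError, ValueError):
    """A configuration value or combination is invalid."""


class ValidationError(AllomemError, ValueError):
    """A data table failed validation; the message names the offending rows."""
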
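"""Exception hierarchy shared across the package."""


class FallowcastError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FallowcastError):
    """Input table is missing required columns or has unusable dtypes."""


class ValidationError(FallowcastError):
    """A record violates a physical or structural invariant."""


class ImputationError(FallowcastError):
    """A gap cannot be filled under the requested policy."""


class IncompleteStageError(FallowcastError):
    """A growth-stage window is missing one or more months."""


class FitError(FallowcastError):
    """A distribution or model fit failed or produced invalid parameters."""


class ConfigError(FallowcastError):
    """Pipeline configuration is missing or inconsistent."""
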
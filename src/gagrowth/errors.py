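"""Exception types shared across the package."""


class GagrowthError(Exception):
    """Base class for package errors."""


class SchemaError(GagrowthError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(GagrowthError):
    """Row-level data problems (negative areas, duplicate timestamps, ...)."""


class ConfigError(GagrowthError):
    """An invalid configuration value (window bounds, probabilities, ...)."""


class DomainError(GagrowthError):
    """Model parameters outside the mean function's declared domain."""


class FitError(GagrowthError):
    """Estimation failed irrecoverably (non-finite posterior at init, ...)."""
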
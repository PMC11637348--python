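"""Exception types shared across the package."""


class ThalamoflowError(Exception):
    """Base class for package errors."""


class ConfigurationError(ThalamoflowError):
    """An incomplete or inconsistent configuration object (e.g., task mapping)."""


class ValidationError(ThalamoflowError):
    """Inputs violate a documented precondition."""


class EstimationError(ThalamoflowError):
    """A model fit cannot proceed (rank deficiency, too few frames, ...)."""


class QCWarning(UserWarning):
    """Data-quality warning (e.g., excessive motion censoring)."""
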
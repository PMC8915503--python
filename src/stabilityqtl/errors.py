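"""Exception types shared across the package."""


class StabilityQtlError(Exception):
    """Base class for package errors."""


class ConfigError(StabilityQtlError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(StabilityQtlError):
    """Inputs violate a documented precondition."""
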
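"""Exception types raised across the package."""


class TwoStepError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TwoStepError, ValueError):
    """Invalid task, population, or fitting configuration."""


class ValidationError(TwoStepError, ValueError):
    """Malformed input data (trial logs, parameter tables)."""


class EstimationError(TwoStepError, RuntimeError):
    """Parameter estimation failed to produce a usable result."""
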
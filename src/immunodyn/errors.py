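"""Exception types shared across the pipeline."""


class ImmunodynError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ImmunodynError):
    """A panel, cohort design, or run configuration is invalid."""


class PairingError(ImmunodynError):
    """Stimulated/unstimulated tables (or time points) do not pair up."""


class ValidationError(ImmunodynError):
    """Input data violate a documented precondition."""
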
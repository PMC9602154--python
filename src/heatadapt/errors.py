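"""Exception hierarchy shared across the pipeline stages."""


class HeatAdaptError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HeatAdaptError):
    """Invalid generator, rule, or pipeline configuration."""


class DataFormatError(HeatAdaptError):
    """A delimited-text table violates the documented schema."""


class DataError(HeatAdaptError):
    """Input observations violate a stage precondition (non-finite values,
    missing phases, empty outcome classes, ...)."""
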
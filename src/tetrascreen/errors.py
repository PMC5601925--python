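"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes (configuration = 2, data /
validation = 3, anything else = 1).
"""


class TetraScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TetraScreenError):
    """A run/panel/scheme configuration is inconsistent or incomplete."""


class CapacityError(ConfigurationError):
    """More antigens (or samples) than the code book can hold."""


class ValidationError(TetraScreenError):
    """Input data violates a documented precondition."""


class DataError(ValidationError):
    """Malformed input file (bad FCS segment, truncated stream, ...)."""


class EmptyInputError(ValidationError):
    """An operation received zero events / zero observations."""
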
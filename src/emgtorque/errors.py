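"""Exception hierarchy.

ConfigError: a parameter set is internally inconsistent or incompatible with the
data (e.g. a band edge at or above Nyquist).  DataError: the data itself is
unusable (empty signal, constant channel, misaligned series).
"""


class EmgTorqueError(Exception):
    """Base class for all package errors."""


class ConfigError(EmgTorqueError, ValueError):
    """Invalid or inconsistent configuration."""


class DataError(EmgTorqueError, ValueError):
    """Input data violates a precondition."""
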
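"""Exception hierarchy for holopop."""


class HolopopError(Exception):
    """Base class for all holopop errors."""


class ConfigurationError(HolopopError):
    """Invalid configuration or parameters."""


class DataError(HolopopError):
    """Malformed or inconsistent input data."""


class ModelError(HolopopError):
    """Statistical model cannot be fitted or applied."""
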
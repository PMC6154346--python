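"""Exception hierarchy for nircal."""


class NircalError(Exception):
    """Base class for all nircal errors."""


class FormatError(NircalError):
    """A delimited-text file violates the expected layout."""


class ConfigurationError(NircalError):
    """A synthetic-data or pipeline configuration is inconsistent."""


class DegenerateSpectrumError(NircalError):
    """A spectrum cannot be processed (e.g. zero variance under SNV)."""


class ParameterError(NircalError):
    """An operation parameter is out of range for the data."""
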
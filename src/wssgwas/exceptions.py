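"""Exception hierarchy shared by all modules.

Exit-code mapping used by the CLI: ConfigurationError -> 2,
DataFormatError -> 3, NumericalError -> 4.
"""


class WssGwasError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WssGwasError):
    """Invalid user configuration (bad field value, missing path, ...)."""


class DataFormatError(WssGwasError):
    """Malformed input file (bad magic bytes, truncated record, ...)."""


class NumericalError(WssGwasError):
    """Numerical failure (singular matrix, non-convergence, ...)."""
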
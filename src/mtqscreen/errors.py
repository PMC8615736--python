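"""Exception hierarchy shared across the toolkit.

``ConfigurationError`` maps to CLI exit code 2, ``DataError`` (and its
subclasses) to exit code 3.
"""


class MtqError(Exception):
    """Base class for all mtqscreen errors."""


class ConfigurationError(MtqError):
    """Invalid configuration: unknown option values, missing columns, bad dialect."""


class DataError(MtqError):
    """Invalid or inconsistent input data."""


class DomainError(DataError):
    """A query falls outside what a fitted object covers.

    Raised e.g. when a record's condition-element value has no
    training-active average, or a model feature is missing from a block.
    """
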
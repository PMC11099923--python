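"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes: usage errors (handled by
click) exit 2, :class:`DataError` and subclasses exit 3, and
:class:`NumericError` exits 4.
"""


class NMRDockError(Exception):
    """Base class for all package errors."""


class DataError(NMRDockError):
    """Invalid, inconsistent or insufficient input data."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending line."""


class GenerationError(NMRDockError):
    """The synthetic-complex builder failed to place the chains."""


class NumericError(NMRDockError):
    """A numeric routine received an out-of-domain value or diverged."""
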
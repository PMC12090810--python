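"""Exception hierarchy shared across the package.

Validation errors (bad inputs, malformed files) and degenerate-statistics
errors (e.g. a constant vector handed to Pearson) are distinguished so the
command-line layer can map them to distinct exit codes.
"""


class ClrSparseError(Exception):
    """Base class for all package errors."""


class ValidationError(ClrSparseError):
    """Input violates a documented precondition (shape, sign, IDs, format)."""


class DegenerateDataError(ClrSparseError):
    """Data is too degenerate for the requested statistic to be defined."""
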
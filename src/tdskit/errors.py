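"""Exception hierarchy.

Every error raised by tdskit derives from :class:`TdsError` so callers (and the
CLI) can map failures to exit codes without string matching.
"""


class TdsError(Exception):
    """Base class for all tdskit errors."""


class ParseError(TdsError):
    """Malformed input file (names the offending line/cell)."""


class SizeError(TdsError):
    """Input too small for the requested operation."""


class DuplicateAxisError(TdsError):
    """Duplicate wavenumber on a spectrum axis."""


class RangeError(TdsError):
    """Requested point/interval outside the data range (no extrapolation)."""


class DomainError(TdsError):
    """Value outside the mathematical domain of an operation."""


class ParameterError(TdsError):
    """Invalid parameter combination."""


class DegeneracyError(TdsError):
    """Numerically degenerate problem (singular system, zero variance, ...)."""


class DataQualityError(TdsError):
    """Input data violates a physical expectation (sign, positivity, ...)."""


class ConsistencyError(TdsError):
    """Inputs that must agree (method, frequency, axis) do not."""


class MaskedValueError(TdsError):
    """Readout requested at a masked (invalid) point."""


class EmptyResultError(TdsError):
    """An operation masked or discarded every point."""


class NotFoundError(TdsError):
    """A required feature (e.g. a peak maximum) was not found."""
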
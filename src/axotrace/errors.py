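"""Exception hierarchy for axotrace.

All domain errors derive from :class:`AxotraceError` so callers can catch the
package's failures with a single except clause; each subclass additionally
derives from the closest builtin (ValueError/KeyError) so generic code keeps
working.
"""


class AxotraceError(Exception):
    """Base class for all axotrace domain errors."""


class InvalidSpecError(AxotraceError, ValueError):
    """A phantom/cohort specification violates its invariants."""


class InvalidImageError(AxotraceError, ValueError):
    """An image contains non-finite pixels or mismatched shapes."""


class InvalidParameterError(AxotraceError, ValueError):
    """An analysis parameter is outside its valid range."""


class NoTissueError(AxotraceError, ValueError):
    """The tissue mask is empty; nothing to analyze."""


class MissingReferenceError(AxotraceError, ValueError):
    """The background reference region is empty."""


class NoDataError(AxotraceError, ValueError):
    """An operation received an empty collection of inputs."""


class DegenerateDataError(AxotraceError, ValueError):
    """Data are degenerate for the requested statistic (e.g. zero variance)."""


class DegenerateDesignError(AxotraceError, ValueError):
    """A factorial design has a factor with fewer than two levels."""


class InsufficientDataError(AxotraceError, ValueError):
    """Not enough observations to estimate the residual (zero residual df)."""


class PairingError(AxotraceError, ValueError):
    """Paired vectors have mismatched lengths."""


class UnknownLevelError(AxotraceError, KeyError):
    """A requested factor level is absent from the table."""


class PackingError(AxotraceError, RuntimeError):
    """Rejection sampling could not place the requested number of cells."""
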
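"""Exception hierarchy for sbecld.

All exceptions derive from :class:`SbecldError` so callers can catch the
package's failures with a single except clause.  The subclasses mirror the
failure modes of the domain: malformed branched structures, degenerate
measurement inputs, invalid physical parameters, and numerical failures of
the calibration or steady-state solvers.
"""


class SbecldError(Exception):
    """Base class for all sbecld errors."""


class StructuralError(SbecldError):
    """A branched glucan violates its structural invariants (cycle, dangling
    link index, attachment position outside the parent segment)."""


class DegenerateInputError(SbecldError, ValueError):
    """An operation received an empty or all-zero distribution where a
    non-degenerate one is required."""


class ParameterError(SbecldError, ValueError):
    """A physical or numerical parameter is outside its valid domain."""


class DataError(SbecldError, ValueError):
    """Input data are inconsistent (e.g. fewer chains after branching)."""


class CalibrationError(SbecldError):
    """SEC calibration could not be established (too few standards,
    non-monotone data) or was used outside its fitted range."""


class ConvergenceError(SbecldError):
    """An iterative solver or fit failed to converge within its caps."""
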
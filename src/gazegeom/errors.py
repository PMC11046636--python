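"""Exception hierarchy shared across the package.

All errors derive from :class:`GazeGeomError` so callers can catch the
package's failures with a single except clause; configuration problems and
data problems are distinguished because the command-line runner maps them
to different exit codes.
"""


class GazeGeomError(Exception):
    """Base class for all gazegeom errors."""


class ConfigurationError(GazeGeomError, ValueError):
    """Invalid parameter values or inconsistent configuration."""


class DataError(GazeGeomError, ValueError):
    """Input data violates a contract (unknown labels, missing pairs, ...)."""


class AlignmentError(DataError):
    """Two per-transition series do not refer to the same transitions."""


class UndefinedCorrelationError(DataError):
    """A correlation is requested on a constant (zero-variance) vector."""


class DegenerateDataError(DataError):
    """Input is degenerate for the requested operation (zero variance,
    rank-deficient design, all-coincident points, ...)."""


class IntegrationError(GazeGeomError, ArithmeticError):
    """Numerical quadrature failed to converge; carries diagnostics."""
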
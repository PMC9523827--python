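"""Typed exceptions shared across the package.

The rank estimators can break down in finite samples (all observations
tied, estimated information shrinking between looks, relative effect on
the boundary of [0, 1]).  Each condition gets its own exception type so
that the simulation engine can apply a configurable policy per event
while interactive use fails loudly.
"""


class GsrankError(Exception):
    """Base class for all package errors."""


class InvalidInputError(GsrankError, ValueError):
    """Malformed or out-of-domain input (empty sample, bad parameter...)."""


class DegenerateVarianceError(GsrankError):
    """A variance estimate is zero, so the information is undefined."""


class BoundaryEffectError(GsrankError):
    """The estimated relative effect sits on {0, 1}; the log win odds
    statistic and its delta-method information are undefined there."""


class MonotonicityError(GsrankError):
    """Estimated information decreased between consecutive analyses."""


class SearchBoundError(GsrankError):
    """A sample-size search exhausted its bounds without reaching the
    requested power."""


class NumericError(GsrankError):
    """A numerical routine (boundary solver, quadrature) failed to
    converge; the message carries diagnostics."""
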
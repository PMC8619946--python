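"""Exception hierarchy shared across the package."""


class DpitrackError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DpitrackError, ValueError):
    """An input violates a documented precondition or invariant."""


class OutOfDomainError(DpitrackError, ValueError):
    """A spatial query lies outside the geometric or interpolation domain."""


class ExtrapolationError(DpitrackError, ValueError):
    """A cumulative-curve query would require extrapolating past the data."""


class FitError(DpitrackError, RuntimeError):
    """A parameter fit failed to converge or is ill-posed."""


class ParseError(DpitrackError, ValueError):
    """A structured input file could not be parsed."""


class NumericalError(DpitrackError, RuntimeError):
    """A trajectory or numeric routine produced non-finite values."""
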
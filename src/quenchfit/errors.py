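"""Exception and warning hierarchy for quenchfit."""


class QuenchfitError(Exception):
    """Base class for all quenchfit errors."""


class ValidationError(QuenchfitError, ValueError):
    """Invalid user input (concentrations, grids, windows, ...)."""


class SolverError(QuenchfitError, RuntimeError):
    """Mass-balance solver failed to converge.

    Attributes
    ----------
    residual : float or None
        Last relative mass-balance residual before giving up.
    point_index : int or None
        Index of the failing titration point, when solving a series.
    """

    def __init__(self, message, residual=None, point_index=None):
        super().__init__(message)
        self.residual = residual
        self.point_index = point_index


class IdentifiabilityError(QuenchfitError, ValueError):
    """The requested parameters cannot be determined from the data."""


class ProtocolError(QuenchfitError, ValueError):
    """A titration protocol cannot be realized (e.g. stock too dilute)."""


class SchemaError(QuenchfitError, ValueError):
    """A data file does not conform to the expected layout."""


class InsufficientDataError(QuenchfitError, ValueError):
    """Too few usable points for the requested regression."""


class QuenchfitWarning(UserWarning):
    """Base class for quenchfit warnings."""


class IdentifiabilityWarning(QuenchfitWarning):
    """The fit is poorly determined (near-singular normal equations,
    too few distinct quencher ratios, ...)."""


class DataWarning(QuenchfitWarning):
    """Suspicious but non-fatal data (dropped points, negative molar
    fluorescences, capacity limits exceeded, ...)."""
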
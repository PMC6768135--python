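"""Exception hierarchy for ligex.

All ligex-specific failures derive from :class:`LigexError` so callers can
catch the package's errors without masking programming errors.
"""


class LigexError(Exception):
    """Base class for all ligex errors."""


class SpeciationError(LigexError):
    """Equilibrium solver failed to reach the residual tolerance.

    Carries the best (smallest) maximum relative mass-balance residual seen,
    so the caller can judge how far from convergence the solve ended.
    """

    def __init__(self, message: str, best_residual: float):
        super().__init__(f"{message} (best max relative residual {best_residual:.3e})")
        self.best_residual = best_residual


class DegenerateFitError(LigexError):
    """A straight-line fit was requested on degenerate data (e.g. all x equal)."""


class ParallelLinesError(LigexError):
    """Two fitted lines are parallel within tolerance; no intersection exists."""


class GeometryUndefinedError(LigexError):
    """The exchange-overlay geometry is undefined (intersection at or below the x-axis)."""


class InsufficientLinearRegionError(LigexError):
    """Too few points survive in the linear (pre-equivalence) region of a series."""


class NoInteriorMaximumError(LigexError):
    """A continuous-variations series has its maximum at an endpoint."""


class InsufficientSegmentError(LigexError):
    """Two-segment regression cannot leave at least two points per segment."""


class SeriesParseError(LigexError):
    """A titration-series file could not be parsed or failed validation."""


class ConfigError(LigexError):
    """Invalid run configuration (unknown preset, missing seed, bad field)."""
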
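"""Exception hierarchy for flymosaic.

All package-specific failures derive from :class:`FlymosaicError` so callers
can catch one base class at CLI boundaries.
"""


class FlymosaicError(Exception):
    """Base class for all flymosaic errors."""


class SpectralFormatError(FlymosaicError):
    """Malformed spectral CSV (non-numeric cells, too few rows, bad ordering)."""


class CoverageError(FlymosaicError):
    """A spectrum does not cover the requested wavelength range."""


class GridMismatchError(FlymosaicError):
    """Spectra that must share a wavelength grid do not."""


class AdaptationError(FlymosaicError):
    """Von Kries adaptation is undefined (a background quantum catch is zero)."""


class DomainError(FlymosaicError):
    """A parameter is outside its admissible domain."""


class InputError(FlymosaicError):
    """Invalid or inconsistent analysis input (empty cloud, unknown level, ...)."""


class DegenerateResponseError(InputError):
    """Binary response is all zeros or all ones."""


class RankError(FlymosaicError):
    """A design or covariance matrix is singular where full rank is required."""


class ConvergenceError(FlymosaicError):
    """An iterative fit failed to converge within its iteration budget."""
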
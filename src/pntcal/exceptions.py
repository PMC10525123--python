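"""Exception and warning types shared across the package."""


class PntCalError(Exception):
    """Base class for all pntcal errors."""


class FormatError(PntCalError, ValueError):
    """A file does not follow the expected CSV/JSON layout."""


class SamplingError(PntCalError, ValueError):
    """A time grid is non-uniform or two grids do not match."""


class UnitError(PntCalError, ValueError):
    """A signal carries a unit label other than the one required."""


class AlignmentError(PntCalError, ValueError):
    """Signals do not overlap in time and cannot be fused."""


class DomainError(PntCalError, ValueError):
    """A physical quantity is outside its admissible range."""


class DegenerateModelError(PntCalError, ValueError):
    """A resistance model with k1 = k2 = 0 cannot be inverted."""


class PhysicalityError(PntCalError, RuntimeError):
    """The simulated barrel state left the physically meaningful region."""


class TrackingError(PntCalError, RuntimeError):
    """The mean-shift tracker lost the marker for too many frames."""


class FitError(PntCalError, ValueError):
    """The calibration design matrix is rank deficient for the order asked."""


class RenderError(PntCalError, ValueError):
    """The synthetic marker would leave the frame bounds."""


class CoverageWarning(UserWarning):
    """Calibration data do not span the pressure range needed for validation."""


class AlignmentWarning(UserWarning):
    """A suspiciously large inter-stream lag was estimated."""


class DirectionWarning(UserWarning):
    """The stated stroke direction disagrees with the displacement trend."""
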
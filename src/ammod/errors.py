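"""Exception hierarchy shared across the toolkit.

All exceptions derive from :class:`AmmodError` so callers can catch the
package's failures with a single clause; each subclass also derives from the
closest builtin (ValueError) so generic handling keeps working.
"""


class AmmodError(Exception):
    """Base class for all ammod errors."""


class InvalidParameterError(AmmodError, ValueError):
    """A parameter is outside its documented domain (e.g. band above Nyquist)."""


class InvalidInputError(AmmodError, ValueError):
    """Input data violate a precondition (empty audio, mismatched lengths...)."""


class IncompatibleSpectraError(AmmodError, ValueError):
    """Two modulation spectra are on different channel or frequency grids."""


class InsufficientDataError(AmmodError, ValueError):
    """Not enough data to compute the requested statistic."""


class CalibrationFailureError(AmmodError, RuntimeError):
    """Depth calibration could not bracket its targets (e.g. silent input)."""


class ScheduleInfeasibleError(AmmodError, ValueError):
    """Trial-schedule constraints cannot be satisfied."""


class DegeneratePeakError(AmmodError, ValueError):
    """Peak search on a spectrum whose maximum is below the noise floor."""
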
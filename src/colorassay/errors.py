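"""Exception hierarchy for the assay pipeline.

All errors derive from :class:`ColorAssayError` so callers can catch the
package's failures with a single except clause; each also derives from the
closest builtin (``ValueError``) so untyped callers fail loudly rather than
silently.
"""


class ColorAssayError(ValueError):
    """Base class for all colorassay errors."""


class InvalidInputError(ColorAssayError):
    """Input data violates a documented precondition (shape, dtype, range)."""


class InsufficientDataError(ColorAssayError):
    """Too few observations or levels to compute the requested statistic."""


class NoPixelsError(ColorAssayError):
    """A region of interest contains no image pixels."""


class DetectionFailureError(ColorAssayError):
    """Automatic spot detection found no usable bright region."""


class NoWorkingRangeError(ColorAssayError):
    """No contiguous run of calibration levels satisfies the linearity rule."""


class UnusableCurveError(ColorAssayError):
    """Calibration curve has non-positive slope and cannot be inverted."""


class UnrepresentableSceneError(ColorAssayError):
    """Synthetic scene parameters imply an intensity outside the 8-bit range."""
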
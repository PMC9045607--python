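"""Exception types shared across the pipeline stages."""


class FilmbendError(Exception):
    """Base class for all package-specific errors."""


class InvalidParamsError(FilmbendError, ValueError):
    """A parameter set violates its invariants (non-finite, wrong sign, ...)."""


class UnknownSolutionError(FilmbendError, KeyError):
    """Requested solution id is not in the composition table."""


class DuplicateSolutionError(FilmbendError, ValueError):
    """An exposure design was requested over non-distinct solution ids."""


class RenderError(FilmbendError, RuntimeError):
    """Filament geometry does not fit on the canvas; names the frame."""


class EmptyFrameError(FilmbendError, ValueError):
    """A frame contains no foreground pixels."""


class TooShortPathError(FilmbendError, ValueError):
    """Fewer usable midline rows than needed to assemble a path."""


class DegenerateTipError(FilmbendError, ValueError):
    """Tip segment has no spatial extent; its direction is undefined."""


class EmptySeriesError(FilmbendError, ValueError):
    """No frame in a sequence produced a usable tip angle."""


class ZeroVarianceError(FilmbendError, ValueError):
    """Shape ensemble has no variance; PCA directions are undefined."""


class UndefinedCorrelationError(FilmbendError, ValueError):
    """Pearson correlation is undefined (constant reference series)."""


class CollinearityError(FilmbendError, ValueError):
    """Regression design matrix is rank deficient."""


class UnderDeterminedError(FilmbendError, ValueError):
    """Too few converged fits to estimate the requested model."""


class TrialMismatchError(FilmbendError, ValueError):
    """Angle-series trial boundaries disagree with the exposure design."""
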
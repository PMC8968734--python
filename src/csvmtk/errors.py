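"""Exception types shared across the toolkit."""


class ToolkitError(Exception):
    """Base class for all csvmtk errors."""


class InvalidSpecError(ToolkitError, ValueError):
    """A phantom or parameter specification violates its invariants."""


class NumericalFailureError(ToolkitError, ArithmeticError):
    """An iterative solver produced non-finite values.

    Carries the iteration index at which the failure was detected.
    """

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class StratificationError(ToolkitError, ValueError):
    """A requested tissue class is absent from the sampling region."""


class TrainingError(ToolkitError, RuntimeError):
    """The SVM dual optimizer failed to converge within its iteration cap."""


class EmptyGLCMError(ToolkitError, ValueError):
    """No valid pixel pair exists for the requested co-occurrence offset."""


class DegenerateFitError(ToolkitError, ValueError):
    """Point correspondences do not determine a rigid transform."""


class FormatError(ToolkitError, IOError):
    """A file could not be read or written in a supported image format."""
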
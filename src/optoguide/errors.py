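"""Exception types shared across the pipeline.

Errors distinguish contract violations (bad arguments) from degenerate data
conditions (rank-deficient fits, cells too thin to ring-mask, cells leaving
the field) so callers can route them differently.
"""


class OptoguideError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(OptoguideError, ValueError):
    """A precondition on an operation's arguments was violated."""


class DegenerateFitError(OptoguideError):
    """A model fit is rank-deficient or otherwise undetermined."""


class ThinCellError(OptoguideError):
    """Eroding a cell mask by the ring contraction emptied it."""


class OutOfFieldError(OptoguideError):
    """A simulated cell left the imaging field.

    Attributes
    ----------
    frame_index : int
        First frame at which the cell footprint exits the field.
    """

    def __init__(self, frame_index: int, message: str | None = None):
        self.frame_index = frame_index
        super().__init__(message or f"cell leaves the field at frame {frame_index}")


class UndefinedHeadingError(OptoguideError):
    """A heading-dependent operation was asked for where no heading exists."""


class NonConvergenceError(OptoguideError):
    """Nonlinear fit failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best_params=None):
        self.best_params = best_params
        super().__init__(message)
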
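"""Exception types shared across the package."""


class GridThetaError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(GridThetaError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(GridThetaError, ValueError):
    """A file violates the data-model invariants; names the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class AlignmentError(GridThetaError, ValueError):
    """Behavioral and signal time ranges cannot be paired."""


class OrientationUndefinedError(GridThetaError, ValueError):
    """Directional regression is rank deficient; no orientation exists."""


class UndefinedMeanError(GridThetaError, ValueError):
    """Circular mean of a perfectly antipodal set has zero resultant."""
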
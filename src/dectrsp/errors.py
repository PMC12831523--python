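"""Exception hierarchy for the dectrsp package."""


class DectrspError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DectrspError, ValueError):
    """An argument violates an operation's preconditions."""


class CalibrationError(DectrspError, ValueError):
    """Not enough (or degenerate) reference materials to calibrate."""


class MaterialTableError(DectrspError, ValueError):
    """A material table could not be parsed; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class GeometryError(DectrspError, ValueError):
    """Phantom geometry is inconsistent (overlap, insert outside outline)."""


class GridMismatchError(DectrspError, ValueError):
    """Two volumes do not share the same grid (shape, spacing, origin)."""


class EvaluationError(DectrspError, ValueError):
    """ROI/statistics evaluation failed (empty ROI, degenerate sample)."""
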
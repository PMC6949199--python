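"""Exception and warning types shared across the pipeline."""


class QDECTError(Exception):
    """Base class for all pipeline errors."""


class DegenerateFitError(QDECTError):
    """Calibration fit attempted with fewer than two distinct concentrations."""


class IllConditionedCalibrationError(QDECTError):
    """Coefficient-matrix determinant below the conditioning floor."""


class SegmentationError(QDECTError):
    """Interface detection failed (no interface, or too many bad columns)."""


class StageError(QDECTError):
    """A pipeline stage aborted; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class PhysicsViolationWarning(UserWarning):
    """Fitted quantity has an unphysical sign or ordering."""
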
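"""Exception hierarchy shared across the package."""


class AngioflowError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(AngioflowError, ValueError):
    """Missing or invalid temporal/spatial calibration."""


class NoBolusError(AngioflowError, ValueError):
    """Time-density curve carries no positive contrast signal to fit."""


class FitError(AngioflowError, RuntimeError):
    """Curve fitting failed to bracket a finite-RMSE solution."""


class FlatCurveError(AngioflowError, ValueError):
    """Curve has no unique maximum above tolerance (peak-to-peak)."""


class ZeroEnergyError(AngioflowError, ValueError):
    """Curve is identically zero; cross-correlation undefined."""


class OrderingError(AngioflowError, ValueError):
    """Best correlation lag is negative: the ROIs appear swapped."""


class EdgeDetectionError(AngioflowError, ValueError):
    """No vessel segment above threshold in a distance-intensity profile."""


class DegenerateMeasurementError(AngioflowError, ValueError):
    """Zero transit time (or other degenerate input) in the flow equation."""


class StageError(AngioflowError, RuntimeError):
    """Pipeline failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {original}")
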
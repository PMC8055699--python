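"""Exception hierarchy shared by the whole package."""


class IrismoothError(Exception):
    """Base class for all package-specific errors."""


class BoundsError(IrismoothError, ValueError):
    """A coordinate or window falls outside the image."""


class SegmentationError(IrismoothError, RuntimeError):
    """Binarization or cleanup could not produce a usable mask."""


class LandmarkError(IrismoothError, ValueError):
    """A landmark could not be snapped onto the border mask."""


class ConnectivityError(IrismoothError, RuntimeError):
    """Geodesic endpoints lie in different connected components."""


class DegenerateMeasurementError(IrismoothError, ValueError):
    """The two endpoints of a side coincide; no length can be measured."""


class SyntheticSpecError(IrismoothError, ValueError):
    """A synthetic-scene specification is internally inconsistent."""


class StageError(IrismoothError, RuntimeError):
    """Wraps a failure so that it names the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[stage: {stage}] {cause}")
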
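"""Exception hierarchy for the quantification pipeline.

Every error that a batch run can recover from (skip the image, fall back to a
pooled control) derives from :class:`StainQuantError` so callers can catch one
base class at the study level.
"""


class StainQuantError(Exception):
    """Base class for all pipeline errors."""


class FormatError(StainQuantError):
    """Input raster is not an 8-bit 3-channel image."""


class LayoutError(StainQuantError):
    """Study directory tree is empty or malformed."""


class CalibrationError(StainQuantError):
    """Dark/Light pair is unusable (shape mismatch or too many invalid pixels)."""


class BasisError(StainQuantError):
    """Stain vectors cannot form an invertible unmixing basis."""


class StainEstimationError(StainQuantError):
    """ROI contains too little stain to estimate a color vector."""


class DegenerateHistogramError(StainQuantError):
    """Variance-based auto-threshold requested on a constant channel."""

    def __init__(self, message: str, constant_value: int | None = None):
        super().__init__(message)
        self.constant_value = constant_value


class AggregationError(StainQuantError):
    """No defined differentiation ratio to aggregate for a donor/condition."""


class ConfigError(StainQuantError):
    """Run configuration is invalid (missing paths, conflicting options)."""


class StudyError(StainQuantError):
    """Study-level failure (more than half of the images failed)."""
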
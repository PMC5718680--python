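"""Exception hierarchy for the epidqc toolkit."""


class EpidQCError(Exception):
    """Base class for all toolkit errors."""


class LayoutError(EpidQCError):
    """Phantom layout violates a structural invariant."""


class OutOfFieldError(EpidQCError):
    """A projected point falls outside the detector panel."""


class CoverageError(EpidQCError):
    """The radiation field or panel does not cover every test element."""


class FormatError(EpidQCError):
    """Unsupported, corrupt, or non-2-D image payload."""


class DetectionError(EpidQCError):
    """No corner-marker blob could be found in the search window."""


class FitError(EpidQCError):
    """Degenerate input to the calibration fit (e.g. collinear points)."""


class GeometryError(EpidQCError):
    """A sampling region (ROI/annulus) is invalid or collides with a neighbor."""


class SaturationError(EpidQCError):
    """Too many pixels at the gray ceiling inside an analysis ROI."""


class AnalysisError(EpidQCError):
    """An analysis has too few usable inputs (e.g. missing wedge steps)."""


class PolarityError(EpidQCError):
    """Gray-scale polarity cannot be determined from the image."""


class ConfigurationError(EpidQCError):
    """Missing or inconsistent run configuration (e.g. no baseline)."""


class InsufficientDataError(EpidQCError):
    """Not enough records for a statistical operation (e.g. trend on 1 point)."""
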
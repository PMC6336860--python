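"""Exception hierarchy shared across the package."""


class VesiclebudError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(VesiclebudError, ValueError):
    """Invalid configuration value."""


class GeometryDomainError(VesiclebudError, ValueError):
    """Operation requested outside its geometric validity domain."""


class DegenerateConfigurationError(GeometryDomainError):
    """Coincident centers or other degeneracy with no unique answer."""


class SegmentationError(VesiclebudError, RuntimeError):
    """No usable object (or several comparable ones) found in a frame."""


class FitError(VesiclebudError, RuntimeError):
    """Circle fitting failed."""


class DegenerateFitError(FitError):
    """Points are collinear or otherwise admit no finite circle."""


class EmptySeriesError(VesiclebudError, ValueError):
    """No frame survived quality control."""


class InsufficientDataError(VesiclebudError, ValueError):
    """Too few frames or samples for the requested statistic."""


class InfeasibleTrajectoryError(VesiclebudError, RuntimeError):
    """Requested area/volume/radius-ratio constraints admit no shape."""


class RenderError(VesiclebudError, ValueError):
    """Shape does not fit inside the frame with the required margin."""


class ValidationError(VesiclebudError, ValueError):
    """Mismatched or corrupt inputs to a comparison step."""
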
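"""Exception hierarchy shared across the package."""


class OrganoflowError(Exception):
    """Base class for all package errors."""


class GeometryError(OrganoflowError):
    """Invalid chamber geometry or an ROI/patch outside the domain."""


class ResolutionError(OrganoflowError):
    """Grid too coarse to resolve a feature (organoid, spot diameter)."""


class SolverError(OrganoflowError):
    """Linear solver failed or returned a non-finite field."""


class StabilityError(OrganoflowError):
    """Requested time step violates the explicit stability bound."""


class CalibrationError(OrganoflowError):
    """Calibration fit impossible (too few or degenerate levels)."""


class InversionError(OrganoflowError):
    """Intensity-to-concentration inversion impossible (zero slope)."""


class SegmentationError(OrganoflowError):
    """Segmentation produced no organoid mask."""


class AlignmentError(OrganoflowError):
    """Timestamp mismatch between series being compared."""


class PlacementError(OrganoflowError):
    """Synthetic spot placement failed at the requested density."""


class ConfigError(OrganoflowError):
    """Configuration validation failure; message names the offending key."""
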
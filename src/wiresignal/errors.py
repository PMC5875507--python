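"""Exception hierarchy.

All package exceptions derive from :class:`WireSignalError` so callers can
catch everything with one clause; the domain/structural split mirrors the
usual ValueError semantics and both subclass ValueError for interoperability.
"""


class WireSignalError(Exception):
    """Base class for all errors raised by wiresignal."""


class InputDomainError(WireSignalError, ValueError):
    """A scalar argument is outside its physical domain (negative MU, ...)."""


class StructuralError(WireSignalError, ValueError):
    """Containers are inconsistent (length mismatch, empty mask, ...)."""


class ConfigError(WireSignalError, ValueError):
    """A configuration file or simulation config is invalid."""


class PlanParseError(WireSignalError, ValueError):
    """A plan file (DICOM or text dialect) could not be parsed."""


class UnsupportedPlanError(PlanParseError):
    """The plan is valid DICOM but not a static step-and-shoot delivery."""


class GeometryMismatchError(StructuralError):
    """Plan geometry does not match the detector (wrong leaf count, ...)."""


class CalibrationError(WireSignalError, ValueError):
    """A parameter fit is degenerate or its inputs are unusable."""


class ComparisonError(WireSignalError, ValueError):
    """Predicted/measured comparison is undefined (all-zero prediction)."""
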
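"""Exception hierarchy.

All holocri errors derive from :class:`HolocriError`; argument-validation
errors additionally derive from :class:`ValueError` so that callers who do
not know about the package hierarchy still catch them idiomatically.
"""


class HolocriError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(HolocriError, ValueError):
    """An argument violates a documented precondition."""


class CapabilityError(HolocriError):
    """The request is outside the numerically supported range."""


class SamplingError(HolocriError, ValueError):
    """The image grid cannot represent the requested optical bandwidth."""


class SidebandOverlapError(HolocriError, ValueError):
    """The fringe carrier is too small to separate the object sideband."""


class DemodulationError(HolocriError):
    """No usable fringe carrier could be found in a hologram."""


class DegenerateCurveError(HolocriError):
    """A scattering curve carries no usable structure (e.g. all zero)."""


class InitializationError(HolocriError):
    """The extrema-matching grid search failed to bracket the data."""


class CalibrationWarning(UserWarning):
    """Cross-wavelength inconsistency detected during sphere calibration."""
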
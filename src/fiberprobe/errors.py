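"""Exception hierarchy for probe-geometry and spectra operations."""


class FiberProbeError(ValueError):
    """Base class for all domain errors raised by this package."""


class InvalidFiberError(FiberProbeError):
    """Fiber parameters outside the guided-ray regime (e.g. NA >= n0)."""


class TiltDomainError(FiberProbeError):
    """Tilt angle at or beyond 90 deg minus the acceptance angle.

    There the effective-distance denominator cos^2(beta) - sin^2(beta) tan^2(theta)
    vanishes and the geometric construction breaks down.
    """


class NoOptimumError(FiberProbeError):
    """Efficiency profile is identically zero; no optimal distance exists."""


class SpectrumParseError(FiberProbeError):
    """Malformed two-column spectrum file; message names the offending line."""


class IntegrationError(FiberProbeError):
    """Requested wavelength band does not intersect the spectrum range."""


class InsufficientDataError(FiberProbeError):
    """Too few points for the requested analysis (e.g. < 3 distances)."""


class UndefinedFractionError(FiberProbeError):
    """Collection fraction requested with zero diffuse reflectance."""
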
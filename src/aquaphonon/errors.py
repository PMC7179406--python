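"""Exception hierarchy.

Every failure mode that callers are expected to handle gets its own class so
that scripts can discriminate without parsing messages.
"""


class AquaphononError(Exception):
    """Base class for all package errors."""


class SpectrumFileError(AquaphononError):
    """The spectrum file is missing or unreadable."""


class SpectrumFormatError(AquaphononError):
    """The spectrum file does not contain two numeric columns."""


class TooFewPointsError(AquaphononError):
    """Fewer than three spectral points; peak detection is undefined."""


class NoPeaksError(AquaphononError):
    """No local maximum passed the prominence threshold."""


class EmptyWindowError(AquaphononError):
    """A required assignment window contains no detected peak."""


class BandEdgeError(AquaphononError):
    """Band edges inconsistent with the given masses (negative discriminant)."""


class DecimationError(AquaphononError):
    """Surface Green's function decimation failed to converge."""


class SingularDeviceError(AquaphononError):
    """Device resolvent is singular; a positive broadening eta is required."""


class QuadratureError(AquaphononError):
    """The heat-flow quadrature did not converge to tolerance."""


class ZeroFrequencyError(AquaphononError):
    """Bose-Einstein occupation diverges at omega = 0."""


class EqualTemperatureError(AquaphononError):
    """Conductance is undefined for equal reservoir temperatures."""


class TemperatureRangeError(AquaphononError):
    """A reservoir temperature would be non-positive."""


class CellSamplingError(AquaphononError):
    """Disorder sampling repeatedly produced an invalid unit cell."""
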
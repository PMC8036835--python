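"""Exception hierarchy shared across the package."""


class RadarVitalsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RadarVitalsError, ValueError):
    """Invalid acquisition or processing parameters."""


class DomainError(RadarVitalsError, ValueError):
    """A physical quantity outside its valid range (e.g. distance beyond dmax)."""


class ShapeError(RadarVitalsError, ValueError):
    """Array axis lengths inconsistent with the configuration."""


class NoMotionDetected(RadarVitalsError):
    """No range bin shows slow-time variance: nothing is moving in front of the radar."""


class UndefinedStatisticError(RadarVitalsError, ValueError):
    """An agreement statistic is undefined for the given input (e.g. zero variance)."""


class BundleError(RadarVitalsError):
    """A dataset bundle on disk is missing, incomplete, or inconsistent."""
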
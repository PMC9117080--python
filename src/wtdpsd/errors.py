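"""Exception types shared across the pipeline stages."""


class WTDPSDError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WTDPSDError, ValueError):
    """Invalid configuration value (unknown wavelet, non-positive lambda, ...)."""


class DimensionError(WTDPSDError, ValueError):
    """Input array has unusable dimensions (empty, or a 1-pixel-wide strip)."""


class ShapeError(WTDPSDError, ValueError):
    """Mutually inconsistent array shapes (subband sets, feature widths)."""


class DegenerateSeriesError(WTDPSDError, ValueError):
    """A subband flattened to an empty pseudo-time series (all coefficients zero)."""


class ShortSeriesError(WTDPSDError, ValueError):
    """Pseudo-time series too short for second differences (length < 3)."""
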
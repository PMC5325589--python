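"""Exception hierarchy shared across the package."""


class LysoQuantError(Exception):
    """Base class for all package errors."""


class PlacementError(LysoQuantError):
    """Synthetic object placement failed (field too small / infeasible)."""


class NoPeakError(LysoQuantError):
    """A spectrum has no resolvable peak (flat or degenerate)."""


class CalibrationError(LysoQuantError):
    """Calibration standards are underdetermined or not invertible."""


class DomainError(LysoQuantError):
    """The analysis domain is empty, constant, or otherwise degenerate."""


class FormatError(LysoQuantError):
    """An input file could not be parsed in the expected format."""


class ConfigError(LysoQuantError):
    """A run configuration is invalid."""
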
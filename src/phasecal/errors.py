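"""Exception hierarchy shared across the package."""


class PhasecalError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PhasecalError):
    """A text input could not be parsed; the message names the offending line."""


class ValidationError(PhasecalError):
    """An input violates a documented invariant (monotonicity, enums, signs...)."""


class CurveRangeError(PhasecalError):
    """A calendar age fell outside calibration-curve support; no extrapolation."""


class GridMismatchError(PhasecalError):
    """Two densities were combined but live on different calendar grids."""


class DegeneratePosteriorError(PhasecalError):
    """All likelihood mass on the grid underflowed; date incompatible with grid."""


class InitializationError(PhasecalError):
    """No finite-posterior starting state could be found for the sampler."""


class DivergenceError(PhasecalError):
    """Terrestrial and marine evidence cannot be reconciled within the prior."""


class UnsupportedOperationError(PhasecalError):
    """The requested report needs a model component that was disabled."""


class ConfigError(PhasecalError):
    """A run configuration is incomplete or references missing paths."""
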
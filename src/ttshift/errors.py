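"""Exception types raised across the package.

All inherit from :class:`TTSError` (itself a ``ValueError``) so callers can
catch the package's errors with a single except clause while ordinary
``ValueError`` semantics are preserved.
"""


class TTSError(ValueError):
    """Base class for all errors raised by ttshift."""


class InvalidRadiusError(TTSError):
    """Truncation radius incompatible with the series length (need n > 2r >= 0)."""


class InvalidShiftError(TTSError):
    """Shift delta outside the admissible range [-r, r]."""


class InvalidLagError(TTSError):
    """Pre-shift lag l with |l| >= n leaves no overlapping data."""


class InsufficientDataError(TTSError):
    """Series too short for the requested operation."""


class DegenerateWindowError(TTSError):
    """A statistic could not be computed on a window (e.g. zero variance)."""


class NoSharedFeaturesError(TTSError):
    """Two multivariate series share no feature identifiers."""


class CannotFillError(TTSError):
    """Gap filling is impossible (e.g. a feature with no observed values)."""


class CircularizationError(TTSError):
    """No feasible (k_start, k_end) pair satisfies the circularization constraints."""


class ConfigError(TTSError):
    """Invalid experiment or test configuration (e.g. duplicate lags)."""


class SimulationError(TTSError):
    """A synthetic system left its valid state space (orbit escape, overflow)."""
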
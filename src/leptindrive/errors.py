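"""Exception hierarchy shared across the package."""


class LeptinDriveError(Exception):
    """Base class for all package errors."""


class DomainError(LeptinDriveError, ValueError):
    """A numeric argument is outside the physically meaningful domain."""


class ConfigError(LeptinDriveError, ValueError):
    """Inconsistent or invalid configuration (schedules, presets, run setup)."""


class DataError(LeptinDriveError, ValueError):
    """Malformed or degenerate input data (weight series, schedules, files)."""


class StatsError(LeptinDriveError, ValueError):
    """A statistic is undefined for the given input (e.g. zero normalizer)."""


class EstimationError(LeptinDriveError, RuntimeError):
    """Parameter estimation failed to produce a usable optimum."""


class SimulationError(LeptinDriveError, RuntimeError):
    """Numerical integration failed; the message carries the failing time."""
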
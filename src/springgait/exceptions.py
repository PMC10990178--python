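"""Exception hierarchy used across the package."""


class SpringGaitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SpringGaitError, ValueError):
    """An argument violates a documented precondition."""


class ModelDomainError(SpringGaitError, ValueError):
    """Inputs are individually valid but outside the model's domain."""


class CalibrationInfeasibleError(SpringGaitError, RuntimeError):
    """No step timing reproduces the requested calibration targets."""


class DataIntegrityError(SpringGaitError, ValueError):
    """Input tables are inconsistent (duplicates, unknown ids, bad labels)."""


class InsufficientDataError(SpringGaitError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedEffectError(SpringGaitError, ValueError):
    """Effect size undefined (e.g. zero pooled standard deviation)."""


class ConfigurationWarning(UserWarning):
    """A configuration is usable but produced degraded behaviour."""
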
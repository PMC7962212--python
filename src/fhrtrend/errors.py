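"""Exception types shared across the pipeline."""


class FhrTrendError(Exception):
    """Base class for all package-specific errors."""


class EmptyEpisodeError(FhrTrendError):
    """An operation required at least one measured FHR sample."""


class OutOfRangeError(FhrTrendError, ValueError):
    """A time fell before the defined grid origin."""


class UndefinedResultError(FhrTrendError):
    """The requested quantity is undefined (e.g. fraction with an empty
    denominator) — deliberately distinct from returning 0."""


class InsufficientDataError(FhrTrendError):
    """A statistical test was asked to run with too few observations."""


class ConfigurationError(FhrTrendError, ValueError):
    """Inconsistent or invalid configuration values."""


class CohortValidationError(FhrTrendError):
    """A cohort manifest failed validation (duplicates, bad fields...)."""
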
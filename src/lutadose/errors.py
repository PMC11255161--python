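"""Exception hierarchy for the dosimetry pipeline."""


class DosimetryError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DosimetryError, ValueError):
    """An argument is outside the physically meaningful domain."""


class FitError(DosimetryError):
    """A time-activity curve fit could not be performed or did not converge."""


class ConfigError(DosimetryError, ValueError):
    """A run or cohort configuration is invalid or infeasible."""
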
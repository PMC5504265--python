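"""Exception hierarchy for the fetalcentiles package."""


class FetalCentilesError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FetalCentilesError):
    """A cohort/simulation configuration field is invalid; the message names it."""


class DomainError(FetalCentilesError):
    """An input falls outside the mathematical domain of an operation."""


class DegenerateDesignError(FetalCentilesError):
    """The regression design matrix is rank deficient (e.g. all ages equal)."""


class DegenerateSDError(FetalCentilesError):
    """The fitted SD curve is zero or negative somewhere it must be positive."""


class IntegrityError(FetalCentilesError):
    """Referential integrity between scans and subjects is broken."""


class ValidationError(FetalCentilesError):
    """A calculator request is inconsistent or implausible."""
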
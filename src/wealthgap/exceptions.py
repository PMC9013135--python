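"""Exception hierarchy for the wealthgap package."""


class WealthgapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WealthgapError):
    """Invalid simulation or run configuration."""


class ValidationError(WealthgapError):
    """Invalid argument to an analysis operation."""


class EstimationError(WealthgapError):
    """An estimate cannot be formed from the data given (e.g. empty subgroup)."""


class DegenerateCompositeError(WealthgapError):
    """The neighbourhood SES composite is undefined (no variance in any ingredient)."""


class SeparationError(EstimationError):
    """Perfect or quasi-perfect separation in a logistic fit."""
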
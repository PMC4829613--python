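"""Exception types shared across the pipeline."""


class LepnormError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LepnormError, ValueError):
    """An invalid configuration field; the message names the field."""


class DomainError(LepnormError, ValueError):
    """An argument outside the mathematical/physical domain of an operation."""


class IntegrityError(LepnormError, ValueError):
    """Structurally inconsistent data (duplicates, mismatched individuals...)."""


class DegenerateDataError(LepnormError, ValueError):
    """Data too degenerate for the requested statistic (zero variance, one class...)."""


class TruncationError(LepnormError, ValueError):
    """An epoch window falling outside the continuous record."""
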
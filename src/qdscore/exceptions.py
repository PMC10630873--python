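"""Exception hierarchy for the qdscore package."""


class QDError(ValueError):
    """Base class for all qdscore errors."""


class DomainError(QDError):
    """A measurement value is outside the mathematical domain of an operation
    (non-positive, non-finite, or a negative golden logarithm)."""


class ConfigurationError(QDError):
    """An indicator registry, threshold scheme, or generator configuration is invalid."""


class ContractError(QDError):
    """An operation was called with a structurally wrong argument set
    (e.g. the liver modification without exactly the four liver-panel indicators)."""


class InputError(QDError):
    """A cohort-level operation received an empty or unusable selection."""
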
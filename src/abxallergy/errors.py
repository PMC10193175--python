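"""Exception hierarchy shared across the pipeline stages."""


class AbxAllergyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AbxAllergyError):
    """A configuration value is missing, malformed, or out of range."""


class ValidationError(AbxAllergyError):
    """A record or table violates its documented schema or domain."""


class IntegrityError(AbxAllergyError):
    """Cross-stage consistency failure (missing keys, mismatched samples)."""


class EstimationError(AbxAllergyError):
    """A statistical quantity cannot be estimated from the given data."""


class ContractError(AbxAllergyError):
    """An operation was called outside its documented precondition."""
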
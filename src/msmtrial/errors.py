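"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation-type failures (schema,
invariant, domain/contract violations) exit 2; estimation failures exit 3.
"""


class MsmTrialError(Exception):
    """Base class for all package errors."""


class SchemaError(MsmTrialError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(MsmTrialError):
    """A record violates a data invariant (names the patient and the rule)."""


class DomainError(MsmTrialError):
    """An argument is outside the function's domain or a contract is broken."""


class EstimationError(MsmTrialError):
    """A statistical model could not be estimated (separation, zero events)."""
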
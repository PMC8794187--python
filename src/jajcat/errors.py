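"""Exception hierarchy shared across the package."""


class JajError(Exception):
    """Base class for all package-specific errors."""


class BankExhaustedError(JajError):
    """No eligible item remains in the bank for the requested selection."""


class NonIdentifiableError(JajError):
    """The response data cannot identify the explanatory model."""


class FitFailureError(JajError):
    """Marginal-likelihood optimisation did not converge."""


class EstimationError(JajError):
    """Ability estimation failed inside the search interval."""


class FormatError(JajError):
    """A serialised artifact violates its schema."""
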
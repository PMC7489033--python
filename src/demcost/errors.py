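"""Exception hierarchy shared across the pipeline."""


class DemcostError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DemcostError):
    """A configuration object violates its invariants."""


class DomainError(DemcostError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class ParseError(DemcostError):
    """A registry file contains a malformed row."""


class EstimationError(DemcostError):
    """Estimation is impossible on the given data (e.g. no transitions at all)."""
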
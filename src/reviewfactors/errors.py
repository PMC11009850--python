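"""Exception hierarchy shared across the pipeline stages."""


class ReviewFactorsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ReviewFactorsError):
    """A configuration value violates its contract (names the offending field)."""


class DataError(ReviewFactorsError):
    """Input data violates a precondition (identifies the offending row/token)."""


class EstimationError(ReviewFactorsError):
    """Model estimation cannot proceed (e.g. rank-deficient design)."""
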
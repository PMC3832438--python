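"""Exception hierarchy shared across the package."""


class ThrombolyzerError(Exception):
    """Base class for all package-specific errors."""


class TraceParseError(ThrombolyzerError):
    """Raised when an input table cannot be parsed into a valid trace."""


class InvalidInputError(ThrombolyzerError, ValueError):
    """Raised when a function receives out-of-contract arguments."""


class AnalysisError(ThrombolyzerError):
    """Raised when an analysis precondition is not met (e.g. missing marker)."""


class FitError(ThrombolyzerError):
    """Raised when a curve fit fails or is ill-posed."""


class SimulationError(ThrombolyzerError):
    """Raised when a simulation cannot be run with the given parameters."""
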
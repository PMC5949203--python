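"""Exception taxonomy shared across the pipeline stages."""


class ROISMiningError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ROISMiningError, ValueError):
    """A parameter value violates an operation's preconditions."""


class InvalidStateError(ROISMiningError, RuntimeError):
    """The input object is in a state the operation cannot act on."""


class EmptyEpochSetError(ROISMiningError, RuntimeError):
    """No usable trials remain (all rejected, or no retainable events)."""


class UndefinedCorrelationError(ROISMiningError, ValueError):
    """Correlation requested for a constant (zero-variance) signal."""


class DegenerateCoherenceError(ROISMiningError, ValueError):
    """Coherence requested with fewer than two spectral segments.

    Single-segment magnitude-squared coherence is identically 1 and
    carries no information, so it is refused rather than returned.
    """


class InvalidPartitionError(ROISMiningError, ValueError):
    """A region-of-interest partition fails validation."""


class DegenerateRegionError(ROISMiningError, RuntimeError):
    """A region has too few surviving channels for the requested feature."""
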
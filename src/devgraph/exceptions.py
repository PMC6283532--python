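"""Exception types shared across devgraph modules."""


class DevgraphError(Exception):
    """Base class for all devgraph errors."""


class ValidationError(DevgraphError):
    """Raised when an input table or registry violates a structural invariant."""


class DegenerateIndicatorError(DevgraphError):
    """Raised when an indicator cannot be scored (constant values, zero SD)."""
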
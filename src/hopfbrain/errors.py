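"""Exception hierarchy for hopfbrain."""


class HopfbrainError(Exception):
    """Base class for all package errors."""


class ParseError(HopfbrainError):
    """Malformed plain-text input (ragged rows, bad tokens, shape mismatch)."""


class ConfigurationError(HopfbrainError):
    """Inconsistent parameters, shapes or preconditions."""


class SimulationError(HopfbrainError):
    """Numerical integration failed (non-finite state)."""


class DegenerateTransitionError(HopfbrainError):
    """Initial and target state fit the target equally well; the normalized
    perturbational score is undefined for this state pair."""
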
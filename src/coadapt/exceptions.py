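"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Invalid input: bad shapes, non-PSD covariances, out-of-range parameters."""


class StationarityError(ValidationError):
    """A transition matrix has spectral radius >= 1, so no stationary state exists."""


class InstabilityError(RuntimeError):
    """A coupled intention/cursor system is unstable (divergent decoder choice)."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance within the iteration cap."""
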
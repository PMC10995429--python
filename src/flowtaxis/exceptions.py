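"""Exception types shared across the package."""


class FlowtaxisError(Exception):
    """Base class for all package-specific errors."""


class SingularMixtureError(FlowtaxisError):
    """Cell volume fraction reached (or exceeded) the singular limit.

    The Darcy drag closure behaves like (1 - phi)**-4, so the stimulus
    diverges as phi -> 1; the mixture equations lose validity well before
    that, hence the solver aborts at a conservative threshold.
    """


class BlowUpError(FlowtaxisError):
    """A time step produced non-finite or strongly negative fields."""

    def __init__(self, message: str, t: float | None = None, dt: float | None = None):
        super().__init__(message)
        self.t = t
        self.dt = dt


class InsufficientDimensionalData(FlowtaxisError):
    """A nondimensional group cannot be formed from the given scales."""
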
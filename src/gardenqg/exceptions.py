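"""Exception types shared across the package."""


class GardenQGError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(GardenQGError, ValueError):
    """A generator or run specification violates its invariants."""


class DegenerateInputError(GardenQGError, ValueError):
    """An input is mathematically degenerate for the requested statistic."""


class IdentifiabilityError(GardenQGError, ValueError):
    """The experimental layout cannot separate the variance components."""


class ConvergenceError(GardenQGError, RuntimeError):
    """An iterative fit failed to converge."""
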
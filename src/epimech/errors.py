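"""Exception hierarchy shared by all epimech modules."""


class EpimechError(Exception):
    """Base class for all epimech errors."""


class TissueValidationError(EpimechError):
    """A tissue violates a structural invariant (dangling ids, bad loops, ...)."""


class TissueParseError(EpimechError):
    """An interchange file could not be parsed into a tissue."""


class ConfigurationError(EpimechError):
    """A model/parameter combination is incomplete or inconsistent."""


class DomainError(EpimechError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateScaleError(EpimechError):
    """Polar back-transform attempted with a nonpositive scale coefficient."""


class DegenerateGeometryError(EpimechError):
    """Geometry too regular to identify parameters (e.g. a perfect hexagonal lattice)."""


class EmptySystemError(EpimechError):
    """Preprocessing or assembly left no usable equations."""


class InstabilityError(EpimechError):
    """Numerical blow-up during relaxation."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite vertex coordinates at step {step}")


class PerfectFitError(EpimechError):
    """Residual variance is exactly zero; AIC is -inf and must be reported separately."""
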
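"""Exception hierarchy shared across hopfnet modules."""


class HopfnetError(Exception):
    """Base class for all hopfnet errors."""


class StructuralError(HopfnetError, ValueError):
    """Input has the wrong shape or structure (e.g. non-square matrix)."""


class ValidationError(HopfnetError, ValueError):
    """Input values violate a precondition (e.g. negative weights)."""


class DivergenceError(HopfnetError, RuntimeError):
    """The numerical integration left the configured stability bound."""

    def __init__(self, step: int, bound: float):
        self.step = step
        self.bound = bound
        super().__init__(
            f"simulation diverged at integration step {step}: |z| exceeded {bound:g}"
        )
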
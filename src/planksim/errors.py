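"""Exception hierarchy shared across planksim modules."""


class PlanksimError(Exception):
    """Base class for all planksim errors."""


class DomainError(PlanksimError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class SlopeSingular(PlanksimError, ZeroDivisionError):
    """A power-law integral is evaluated at its singular slope."""


class ConvergenceError(PlanksimError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class DimensionError(PlanksimError, ValueError):
    """Mismatched array lengths between coupled state vectors."""


class DegenerateEquilibrium(PlanksimError, ValueError):
    """No positive coexistence equilibrium exists for the given rates."""


class NegativeStock(PlanksimError, RuntimeError):
    """A state variable went negative during integration (reduce dt)."""


class NonFinite(PlanksimError, RuntimeError):
    """Integration produced NaN or infinite state."""


class DegenerateFit(PlanksimError, ValueError):
    """Too few usable points to fit a line or curve."""


class SchemaError(PlanksimError, ValueError):
    """Configuration contains an unknown or invalid key."""

    def __init__(self, message: str, key_path: str | None = None):
        super().__init__(message)
        self.key_path = key_path
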
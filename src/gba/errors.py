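"""Exception hierarchy for growth balance analysis."""


class GBAError(Exception):
    """Base class for all errors raised by this package."""


class InputError(GBAError):
    """Malformed or inconsistent user input (masses, dimensions, identifiers)."""


class MassBalanceError(GBAError):
    """A stoichiometric column is not mass balanced in the closed system.

    Raised instead of silently rebalancing: a mass-imbalanced column usually
    means a ubiquitous reactant (e.g. water) was omitted from the input.
    """

    def __init__(self, column: str, residual: float):
        self.column = column
        self.residual = residual
        super().__init__(
            f"column {column!r} is not mass balanced: mass-weighted sum "
            f"{residual:.3e} != 0"
        )


class ValidationError(GBAError):
    """A model failed structural validation; carries the full report."""

    def __init__(self, report):
        self.report = report
        failed = ", ".join(c.name for c in report.failures())
        super().__init__(f"model validation failed: {failed}")


class KineticsDomainError(GBAError):
    """A kinetic law was evaluated at a non-positive required concentration."""

    def __init__(self, reaction: str, reactant: str, value: float):
        self.reaction = reaction
        self.reactant = reactant
        self.value = value
        super().__init__(
            f"turnover time of reaction {reaction!r} undefined: concentration "
            f"of {reactant!r} is {value:.3e} (must be > 0)"
        )


class SingularTurnoverError(GBAError):
    """A turnover time is singular (thermodynamic equilibrium or zero denominator)."""


class InfeasibleModelError(GBAError):
    """No interior point satisfies the density and concentration constraints."""


class OptimizationFailureError(GBAError):
    """No optimization start converged to a feasible stationary point."""

    def __init__(self, message: str, starts=None):
        self.starts = starts or []
        super().__init__(message)


class ModelFormatError(GBAError):
    """A model file could not be parsed or is structurally incomplete."""
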
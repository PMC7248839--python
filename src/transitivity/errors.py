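"""Exception hierarchy for the transitivity package."""


class TransitivityError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TransitivityError, ValueError):
    """A rate-law parameter violates its constraints (e.g. A <= 0, s < 1)."""


class DomainError(TransitivityError, ValueError):
    """Evaluation was requested outside a law's domain of validity."""


class SingularTransitivityError(TransitivityError, ZeroDivisionError):
    """Transitivity is undefined: the apparent activation energy vanishes."""


class NoFiniteLimitError(TransitivityError):
    """Sub-Arrhenius laws (d <= 0) have no finite lower thermal limit."""


class NotApplicableError(TransitivityError):
    """The requested diagnostic does not apply to this parameter regime."""


class NumericalError(TransitivityError, ArithmeticError):
    """A quadrature or iterative scheme failed to converge."""


class InputError(TransitivityError, ValueError):
    """User-supplied data violate an input contract."""


class FitFailureError(TransitivityError, RuntimeError):
    """No optimisation start converged; diagnostics are attached as args."""


class InvalidSpecError(TransitivityError, ValueError):
    """A synthetic-data specification is internally inconsistent."""


class ConfigError(TransitivityError, ValueError):
    """Run configuration failed validation."""
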
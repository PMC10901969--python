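"""Exception hierarchy for vasotone."""


class VasotoneError(Exception):
    """Base class for all package-specific errors."""


class DomainError(VasotoneError, ValueError):
    """An input lies outside the admissible domain of an operation."""


class GeometryError(VasotoneError, ValueError):
    """Invalid or inconsistent vessel-wall geometry."""


class SingularEquilibriumError(VasotoneError, ArithmeticError):
    """The pLC20 steady state is 0/0 (kinase fully off while phosphatase
    is fully inhibited); no equilibrium fraction is defined."""


class SolverError(VasotoneError, RuntimeError):
    """Coupled chemo-mechanical equilibrium solve failed to converge.

    Carries the last iterate and residuals for diagnostics.
    """

    def __init__(self, message, last_iterate=None, residuals=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.residuals = residuals


class ConfigError(VasotoneError, ValueError):
    """Parameter/configuration file violates the schema or a hard bound."""


class CoverageError(VasotoneError, ValueError):
    """Simulated observables do not cover every requested data row."""
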
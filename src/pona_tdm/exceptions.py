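"""Exception hierarchy shared across the package."""


class PonaTdmError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PonaTdmError, ValueError):
    """An input lies outside the mathematical/clinical domain of an operation."""


class ConvergenceError(PonaTdmError, RuntimeError):
    """An iterative procedure failed to reach its declared tolerance."""


class DegenerateTableError(DomainError):
    """A contingency table has a zero margin, so an exact test is undefined."""


class EnumerationLimitError(PonaTdmError, RuntimeError):
    """Exact enumeration would exceed the configured table-count guard."""


class UndefinedStatisticError(DomainError):
    """The requested statistic is undefined for the given data (e.g. constant ranks)."""


class SchemaError(PonaTdmError, ValueError):
    """Tabular input violates the expected schema; carries itemised messages."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class FixtureInfeasibleError(PonaTdmError, RuntimeError):
    """The published marginal counts admit no joint allocation (should not happen)."""
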
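"""Exception hierarchy for riskmix."""


class RiskmixError(Exception):
    """Base class for all riskmix errors."""


class ValidationError(RiskmixError):
    """Invalid input data or malformed domain objects."""


class DomainError(RiskmixError):
    """A parameter or argument outside the mathematical domain of an operation."""


class ConvergenceError(RiskmixError):
    """Optimizer failed to converge, or the solution is degenerate."""


class DegenerateComparisonError(RiskmixError):
    """A model-comparison test is undefined (e.g. identical likelihood paths)."""
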
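"""Exception hierarchy for relmech.

All validation failures raise subclasses of :class:`RelmechError` so callers
(and the CLI) can distinguish bad input from genuine bugs.
"""


class RelmechError(Exception):
    """Base class for all relmech errors."""


class DomainError(RelmechError, ValueError):
    """An argument lies outside the physical/mathematical domain of an operation."""


class ConstraintViolationError(RelmechError, ValueError):
    """A structural constraint (e.g. mechanism weights summing to 1) is violated."""


class InputError(RelmechError, ValueError):
    """Malformed or insufficient user input (too few points, bad shapes...)."""


class DegenerateDataError(InputError):
    """Data carry no information for the requested operation (e.g. zero variance)."""


class FormatError(InputError):
    """A file does not conform to the expected on-disk format."""


class InfeasibleSubproblemError(RelmechError):
    """The linearized QP subproblem has no feasible point."""
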
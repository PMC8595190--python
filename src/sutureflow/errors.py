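"""Exception hierarchy.

Every failure mode the solvers can report maps to one of these, so callers
(and the CLI, which maps them to exit statuses) can discriminate between
"your request is physically impossible" and "the numerics did not converge".
"""


class SutureflowError(Exception):
    """Base class for all package errors."""


class UnitError(SutureflowError):
    """Unknown unit symbol or dimensionally inconsistent conversion."""


class GeometryError(SutureflowError):
    """Invalid or degenerate cross-section geometry."""


class InfeasibleError(SutureflowError):
    """The requested target violates a physical bound of the model.

    The message names the violated bound (e.g. a target IOP at or above the
    pre-surgery IOP, or a resistance ratio below 1).
    """


class NumericalAccuracyError(SutureflowError):
    """A numerical result failed its own error-estimate tolerance."""
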
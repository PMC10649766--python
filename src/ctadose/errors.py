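"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`CtaDoseError`, so callers (and the CLI) can distinguish data or
usage problems from genuine bugs.
"""


class CtaDoseError(Exception):
    """Base class for all errors raised by ctadose."""


class ValidationError(CtaDoseError):
    """An input value violates a documented precondition."""


class InvalidBoundsError(ValidationError):
    """Factor bounds are degenerate (x_max <= x_min) or non-finite."""


class OutOfRangeError(ValidationError):
    """A reading falls outside its factor bounds under the strict policy."""


class RankDeficiencyError(CtaDoseError):
    """The design matrix does not have full column rank.

    Carries the labels of the collinear columns in ``columns``.
    """

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = columns


class UnderdeterminedError(CtaDoseError):
    """Fewer observations than coefficients."""


class ZeroSensitivityError(CtaDoseError):
    """The contrast-media dose does not influence the predicted CTA number."""


class SchemaError(CtaDoseError):
    """A file is missing required columns or fields."""


class IncompatibleModelError(CtaDoseError):
    """A model file disagrees with the canonical 29-term layout."""


class CohortSpecError(ValidationError):
    """A synthetic-cohort specification is infeasible."""
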
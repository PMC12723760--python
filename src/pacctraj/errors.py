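"""Exception hierarchy used across the pipeline."""


class PacctrajError(Exception):
    """Base class for all package errors."""


class SchemaError(PacctrajError):
    """A required column or field is missing from an input table."""


class ReferentialError(PacctrajError):
    """A subject appears in one table but not its companion."""


class ValidationError(PacctrajError):
    """Input values violate a documented invariant."""


class SpecificationError(PacctrajError):
    """A model or simulation specification is invalid."""


class DegenerateInputError(PacctrajError):
    """Input is constant/collinear where variation is required."""


class MissingDataError(PacctrajError):
    """Required measurements are absent for a subject."""


class RangeError(PacctrajError):
    """Values fall outside the mathematical domain of a transform."""


class ConvergenceError(PacctrajError):
    """No optimizer start reached the convergence criteria."""

    def __init__(self, message, best_state=None):
        super().__init__(message)
        self.best_state = best_state
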
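"""Exception hierarchy shared across the package."""


class MciscoreError(Exception):
    """Base class for all package errors."""


class FormatError(MciscoreError, ValueError):
    """A table does not conform to the declared format (missing columns, ...)."""


class RowParseError(FormatError):
    """A single row failed to parse; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class InputError(MciscoreError, ValueError):
    """Invalid input to an operation."""


class DegenerateInputError(InputError):
    """Input on which the requested statistic is undefined."""


class DegenerateCovariateError(DegenerateInputError):
    """A covariate has zero variance and is unidentifiable."""


class ConvergenceError(MciscoreError, RuntimeError):
    """Iterative fit failed to converge."""


class ParameterError(InputError):
    """Invalid parameter value (e.g. non-positive point constant B)."""


class ExtrapolationError(InputError):
    """A survival probability was requested beyond the observed follow-up."""


class UndefinedMetricError(InputError):
    """Metric undefined for this input (e.g. AUC with one outcome class)."""


class RiskParametersUnavailableError(MciscoreError):
    """Instrument carries no absolute-risk parameters (bands only)."""


class OutOfRangeError(InputError):
    """A profile value lies outside the instrument's supported domain."""


class UnsupportedCategoryError(InputError):
    """A profile value has no category in the instrument (e.g. CDR > 0.5)."""


class MissingFieldError(InputError):
    """A required profile field is missing."""
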
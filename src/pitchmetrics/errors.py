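"""Exception hierarchy shared across the package.

Exit codes (used by the CLI): 2 configuration/domain errors, 3 input
validation/selection errors, 4 degenerate computations.
"""


class AnalysisError(Exception):
    """Base class for all pitchmetrics errors."""

    exit_code = 1
    code = "error"


class ConfigError(AnalysisError):
    """Invalid configuration or request (bad parameters, unknown names)."""

    exit_code = 2
    code = "config"


class DomainError(ConfigError):
    """A value outside its mathematical/physical domain (negative speed,
    point off the pitch, unknown pace label or scenario)."""

    code = "domain"


class GroupSizeError(ConfigError):
    """Group smaller than the minimum required for the requested metric."""

    code = "group-size"


class ValidationError(AnalysisError):
    """Input data violates the positional-dataset contract."""

    exit_code = 3
    code = "validation"


class FormatError(ValidationError):
    """Input file does not match the documented CSV layout."""

    code = "format"


class EmptyInputError(ValidationError):
    code = "empty-input"


class EmptySelectionError(ValidationError):
    """A slice or player selection matched no records."""

    code = "empty-selection"


class SelectionError(ValidationError):
    """Invalid group composition (overlapping groups, unknown players)."""

    code = "selection"


class AlignmentError(ValidationError):
    """Samples cannot be aligned onto a common time grid."""

    code = "alignment"


class DegenerateError(AnalysisError):
    """The computation is undefined on this input."""

    exit_code = 4
    code = "degenerate"


class DegenerateSignalError(DegenerateError):
    """Constant (or near-constant) signal: instantaneous phase undefined."""

    code = "degenerate-signal"


class InsufficientDataError(DegenerateError):
    """Too few samples for the requested computation."""

    code = "insufficient-data"
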
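"""Exception hierarchy shared across the package."""


class AdescreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AdescreenError):
    """An input table is malformed (missing columns, duplicate headers, ...)."""


class ValidationError(AdescreenError):
    """Input data or configuration violates a documented precondition."""


class UndefinedStatisticError(AdescreenError):
    """A statistic is undefined for the given counts (e.g. zero margin)."""


class DegenerateError(AdescreenError):
    """An evaluation is degenerate (e.g. ROC with no negatives, constant-x fit)."""


class StageError(AdescreenError):
    """A pipeline stage failed; carries the stage name for user-facing messages."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
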
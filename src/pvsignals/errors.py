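"""Exception hierarchy shared across the package."""


class PvSignalsError(Exception):
    """Base class for all package errors."""


class InputError(PvSignalsError):
    """A required input file is missing or unreadable."""


class ConfigurationError(PvSignalsError):
    """The run configuration or a mapping is invalid or incomplete."""


class DegenerateInputError(PvSignalsError):
    """The input is structurally empty for the requested computation
    (e.g. an all-zero contingency table or an empty subgroup)."""


class UndefinedEstimateError(PvSignalsError):
    """A point estimate is undefined for these counts (zero cell without a
    continuity correction).  ``cell`` names the offending cell."""

    def __init__(self, message: str, cell: str | None = None):
        super().__init__(message)
        self.cell = cell


class ConvergenceError(PvSignalsError):
    """An iterative fit failed to converge; ``trace`` carries the objective
    history for diagnosis."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class PipelineError(PvSignalsError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
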
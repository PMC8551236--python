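"""Exception hierarchy shared across the package."""


class PDGaitError(Exception):
    """Base class for all package errors."""


class DomainError(PDGaitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InsufficientDataError(PDGaitError, ValueError):
    """Too few observations to compute the requested quantity."""


class ConfigError(PDGaitError, ValueError):
    """Invalid generator or pipeline configuration."""


class GenerationError(PDGaitError, RuntimeError):
    """Synthetic data could not be generated from the given targets."""


class DegenerateInputError(PDGaitError, ValueError):
    """Numerically degenerate input (e.g. singular correlation matrix)."""


class SchemaError(PDGaitError, ValueError):
    """A table does not conform to the documented column schema."""


class PipelineStageError(PDGaitError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
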
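"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An input, parameter, or channel selection is invalid."""


class ParseError(RuntimeError):
    """A file could not be read as a valid recording container."""


class DegenerateSignalError(ValueError):
    """A computation received an input it is undefined for (zero power,
    constant sample, zero pooled variance, ...)."""


class ArchitectureError(RuntimeError):
    """Constructed network does not match the reference layer table."""


class TrainingDivergedError(RuntimeError):
    """Training produced a non-finite loss."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
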
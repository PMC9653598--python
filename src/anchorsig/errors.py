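"""Exception hierarchy shared across the package."""


class AnchorsigError(Exception):
    """Base class for all errors raised by anchorsig."""


class ValidationError(AnchorsigError, ValueError):
    """An input object violates one of its invariants."""


class FormatError(AnchorsigError, ValueError):
    """A file could not be parsed; the message carries path and line number."""


class ConfigError(AnchorsigError, ValueError):
    """A pipeline configuration is invalid; the message names the field."""


class PipelineError(AnchorsigError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
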
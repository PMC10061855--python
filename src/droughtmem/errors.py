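"""Exception hierarchy shared across the package."""


class DroughtMemError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DroughtMemError):
    """Invalid simulation or pipeline configuration."""


class LoadError(DroughtMemError):
    """A file could not be parsed or failed validation on load."""


class InvalidRecordError(DroughtMemError):
    """A data record violates its invariants (e.g. mass ordering)."""


class StageError(DroughtMemError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
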
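"""Exception hierarchy shared across the pipeline stages."""


class TagDGEError(Exception):
    """Base class for all package errors."""


class InputError(TagDGEError):
    """Invalid user-supplied data or parameters (CLI exit code 2)."""


class InvalidConfigError(InputError):
    """A configuration object violates its invariants."""


class StageError(TagDGEError):
    """A pipeline stage failed; carries the stage name (CLI exit code 3)."""

    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
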
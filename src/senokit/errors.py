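"""Exception hierarchy shared across senokit modules."""


class SenokitError(Exception):
    """Base class for all senokit errors."""


class ConfigurationError(SenokitError, ValueError):
    """A simulator or pipeline configuration is invalid.

    The message names the offending field(s).
    """


class DataValidationError(SenokitError, ValueError):
    """An input table violates its contract (duplicate IDs, bad values, ...)."""


class StageError(SenokitError, RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
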
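"""Exception types shared across mbnet modules."""


class MbnetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MbnetError, ValueError):
    """An input file violates its expected layout or value ranges."""


class ConfigError(MbnetError, ValueError):
    """A configuration value is out of range; the message names the field."""


class PipelineError(MbnetError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")
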
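"""Exception hierarchy shared across the pipeline."""


class SpecfxError(Exception):
    """Base class for all package errors."""


class ConfigError(SpecfxError, ValueError):
    """A configuration field is invalid; the message names the field."""


class ParseError(SpecfxError, ValueError):
    """An input file could not be parsed; includes the offending line."""


class ValidationError(SpecfxError, ValueError):
    """Parsed data violate a structural invariant (e.g. non-positive area)."""


class FitError(SpecfxError, RuntimeError):
    """A model fit failed (degenerate input, divergence, ...)."""


class PipelineError(SpecfxError, RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
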
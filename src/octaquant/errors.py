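"""Exception hierarchy shared by all modules."""


class OctaquantError(Exception):
    """Base class for package errors."""


class ValidationError(OctaquantError, ValueError):
    """Invalid input values, shapes, or configuration."""


class PipelineStageError(OctaquantError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
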
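"""Exception hierarchy shared across the pipeline."""


class CardioT2StarError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CardioT2StarError, ValueError):
    """Invalid parameter or configuration value."""


class FormatError(CardioT2StarError):
    """Malformed or incomplete on-disk data (missing sidecar, bad table)."""


class ConsistencyError(CardioT2StarError):
    """Internally inconsistent data (frame counts, geometry mismatch)."""


class StageError(CardioT2StarError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
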
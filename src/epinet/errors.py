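"""Exception types shared across the pipeline stages."""


class EpinetError(Exception):
    """Base class for all package errors."""


class ConfigError(EpinetError, ValueError):
    """A simulation or pipeline configuration field is invalid."""


class FormatError(EpinetError, ValueError):
    """An input file violates its expected dialect or schema."""


class StructuralError(EpinetError, ValueError):
    """An in-memory object violates a structural precondition
    (e.g. a count table with no control samples, a cyclic hierarchy)."""


class StageError(EpinetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
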
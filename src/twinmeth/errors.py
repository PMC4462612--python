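"""Exception hierarchy.

All package errors derive from :class:`TwinMethError` so callers (and the
CLI) can distinguish data problems from genuine bugs.
"""


class TwinMethError(Exception):
    """Base class for all errors raised by twinmeth."""


class ParseError(TwinMethError):
    """A file could not be parsed; the message names the offending location."""


class DataValidationError(TwinMethError):
    """Parsed data violates a documented invariant."""


class AnalysisError(TwinMethError):
    """An analysis precondition is not met (e.g. too few pairs)."""


class StageError(TwinMethError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage:{stage}] {message}")
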
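"""Exception hierarchy for touchscore.

Parse/validation errors carry enough context (line number, pointer id,
session identity) for a batch runner to report which input failed.
"""

from __future__ import annotations


class TouchscoreError(Exception):
    """Base class for all package-specific errors."""


class StreamParseError(TouchscoreError):
    """A JSONL event log line could not be parsed."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class StreamValidationError(TouchscoreError):
    """An event stream violates the per-pointer phase grammar or bounds."""

    def __init__(self, message: str, pointer_id: int | None = None):
        self.pointer_id = pointer_id
        if pointer_id is not None:
            message = f"pointer {pointer_id}: {message}"
        super().__init__(message)


class UnscorableError(TouchscoreError):
    """A structurally valid session has no scorable content.

    Distinct from a score of zero: e.g. a pincer trial in which no instant
    ever had exactly two concurrent contacts.
    """


class IncompleteTrialError(UnscorableError):
    """An oculo-manual trial ended before all targets were acquired."""

    def __init__(self, acquired: int, total: int, message: str | None = None):
        self.acquired = acquired
        self.total = total
        super().__init__(
            message or f"only {acquired} of {total} targets acquired"
        )


class UndefinedStatisticError(TouchscoreError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
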
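"""Exception hierarchy for trial allocation.

Every error a caller can act on derives from :class:`TrialError` so that a
CLI or web layer can distinguish user-fixable problems (validation, config)
from corrupted trial state, which must never be silently repaired.
"""

from __future__ import annotations


class TrialError(Exception):
    """Base class for all package errors."""


class ValidationError(TrialError, ValueError):
    """One or more submitted fields are invalid.

    ``problems`` carries every individual problem so intake can report all
    of them at once rather than one per round trip.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class ConfigurationError(TrialError):
    """Trial configuration is internally inconsistent or out of range."""


class SchemeMismatchError(TrialError):
    """A vector or aggregate does not match the factor scheme in use."""


class CorruptHistoryError(TrialError):
    """An allocation record or state-file line violates its invariants."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class SerializationError(TrialError):
    """A record cannot be written as a delimited line (delimiter collision)."""


class DuplicateParticipantError(TrialError):
    """The participant ID already appears in the allocation history."""


class DoubleAllocationError(TrialError):
    """Attempt to finalize a class vector that already carries an outcome."""


class ReconstructionError(TrialError):
    """A backup message does not contain a recoverable state-file block."""


class LockTimeoutError(TrialError):
    """Could not obtain the exclusive state-file lock in time."""
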
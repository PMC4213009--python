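"""Notification rendering and dispatch.

Each successful allocation composes three plain-text messages: one to the
submitter, one to the study nurse (a copy of the first), and one to the
study administrator. The administrator message additionally embeds the
newly appended state line and the full state-file content between marker
lines, so every allocation distributes a complete, independently
reconstructable backup of the trial.

Message *transport* is a pluggable interface; the package ships a recording
transport (for tests and dry runs) and a file transport that writes each
message into an outbox directory. Actual mail delivery is deployment
plumbing and deliberately out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Protocol

from .core import AllocationRecord
from .errors import ValidationError
from .scheme import FactorScheme
from .state import BACKUP_BEGIN, BACKUP_END, DEFAULT_DELIMITER, format_line

RESEARCHER_EMAIL_LINES = 18


@dataclass(frozen=True)
class TrialCounts:
    total: int
    control: int
    experimental: int


@dataclass(frozen=True)
class Message:
    recipient: str
    subject: str
    body: str


class Transport(Protocol):
    """Anything that can deliver a composed message."""

    def send(self, message: Message) -> None: ...


class RecordingTransport:
    """Collects messages in memory; the default for tests and dry runs."""

    def __init__(self):
        self.sent: list[Message] = []

    def send(self, message: Message) -> None:
        self.sent.append(message)


class FileTransport:
    """Writes each message to ``outbox/<seq>_<recipient>.txt``."""

    def __init__(self, outbox: str | Path):
        self.outbox = Path(outbox)

    def send(self, message: Message) -> None:
        self.outbox.mkdir(parents=True, exist_ok=True)
        seq = len(list(self.outbox.glob("*.txt")))
        safe = re.sub(r"[^A-Za-z0-9_.-]+", "_", message.recipient)
        path = self.outbox / f"{seq:05d}_{safe}.txt"
        path.write_text(
            f"To: {message.recipient}\nSubject: {message.subject}\n\n{message.body}",
            encoding="utf-8",
        )


@dataclass(frozen=True)
class NotificationReport:
    messages: tuple[Message, ...]
    failures: tuple[str, ...] = ()


def _require_renderable(record: AllocationRecord) -> None:
    if not record.vector.is_finalized:
        raise ValidationError("record is not finalized: no outcome flag set")
    if record.submission is None:
        raise ValidationError(
            "record carries no submission details; notifications can only be "
            "rendered at allocation time"
        )


def render_researcher_email(
    record: AllocationRecord,
    counts: TrialCounts,
    scheme: FactorScheme,
    r: float,
    trial_name: str = "study",
) -> Message:
    """The 18-line allocation notification sent to the submitter.

    States the submitted variables and the outcome, plus the running arm
    counts — and nothing about previous participants, keeping the message
    small. The subject line carries the ISO date.
    """
    _require_renderable(record)
    s = record.submission
    body_lines = [
        f"Participant allocation notification ({trial_name})",
        f"Date: {record.date}",
        f"Weekday: {record.weekday}",
        f"Time: {s.time}",
        f"Participant ID: {record.participant_id}",
        f"Submitted by: {record.submitter}",
        f"Gender: {s.gender}",
        f"Age: {s.age_years}",
        f"Age class: {s.age_class}",
        f"Diabetes: {s.diabetes}",
        f"Ethnicity (detailed): {s.ethnicity_code}",
        f"Ethnicity (aggregated): {s.ethnicity}",
        f"Allocation: {scheme.arm_label(record.arm)}",
        f"Total allocated: {counts.total}",
        f"Control arm: {counts.control}",
        f"Experimental arm: {counts.experimental}",
        f"Randomization element: {r}",
        "End of notification",
    ]
    assert len(body_lines) == RESEARCHER_EMAIL_LINES
    return Message(
        recipient=record.submitter,
        subject=f"Allocation {record.date}: participant {record.participant_id}",
        body="\n".join(body_lines),
    )


def render_admin_email(
    record: AllocationRecord,
    history_text: str,
    counts: TrialCounts,
    scheme: FactorScheme,
    r: float,
    trial_name: str = "study",
    delimiter: str = DEFAULT_DELIMITER,
) -> Message:
    """The administrator message: notification plus a full-history backup.

    Contains everything the submitter message does, then the state line just
    appended and the entire state-file content verbatim between markers —
    an independent backup from which the trial can be reconstructed even if
    every file on the server is lost (see ``state.rebuild_from_backup``).
    """
    researcher = render_researcher_email(record, counts, scheme, r, trial_name)
    if not history_text.endswith("\n") and history_text != "":
        history_text += "\n"
    body = (
        researcher.body
        + "\n\nAppended state line:\n"
        + format_line(record, scheme, delimiter)
        + f"\n\n{BACKUP_BEGIN}\n{history_text}{BACKUP_END}\n"
    )
    return Message(
        recipient=researcher.recipient,
        subject=researcher.subject + " [full history]",
        body=body,
    )


def dispatch_notifications(
    record: AllocationRecord,
    counts: TrialCounts,
    history_text: str,
    scheme: FactorScheme,
    r: float,
    nurse: str,
    admin: str,
    extra_recipients=(),
    transport: Transport | None = None,
    trial_name: str = "study",
    delimiter: str = DEFAULT_DELIMITER,
) -> NotificationReport:
    """Compose and hand off the default three messages (plus any extras).

    Submitter and nurse receive identical content; the administrator
    receives the full-history variant. Transport failures are reported but
    never roll back the allocation — allocation truth lives in the state
    file, not in the mail stream.
    """
    transport = transport if transport is not None else RecordingTransport()
    researcher = render_researcher_email(record, counts, scheme, r, trial_name)
    admin_msg = render_admin_email(
        record, history_text, counts, scheme, r, trial_name, delimiter
    )
    messages = [
        researcher,
        replace(researcher, recipient=nurse),
        replace(admin_msg, recipient=admin),
    ]
    messages.extend(replace(researcher, recipient=addr) for addr in extra_recipients)
    failures = []
    for msg in messages:
        try:
            transport.send(msg)
        except Exception as exc:  # delivery must never undo an allocation
            failures.append(f"{msg.recipient}: {exc}")
    return NotificationReport(tuple(messages), tuple(failures))
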
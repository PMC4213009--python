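"""The allocation transaction: load history, decide, persist, notify.

One engine instance serves one trial. Each allocation runs under an
exclusive advisory lock on a sidecar lock file, so concurrent submissions
from multiple sites serialize: every decision sees the complete history of
all previous allocations.
"""

from __future__ import annotations

import datetime as _dt
import fcntl
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import core, state
from .config import EngineConfig
from .errors import DuplicateParticipantError, LockTimeoutError
from .intake import ParticipantSubmission, stamp_submission
from .reporting import (
    FileTransport,
    Message,
    NotificationReport,
    Transport,
    TrialCounts,
    dispatch_notifications,
)
from .scheme import OPTION1

logger = logging.getLogger(__name__)


@contextmanager
def exclusive_lock(target: Path, timeout: float = 10.0):
    """Advisory exclusive lock on ``<target>.lock``; waits up to ``timeout`` s."""
    lock_path = target.with_suffix(target.suffix + ".lock")
    lock_path.parent.mkdir(parents=True, exist_ok=True)
    fh = lock_path.open("a")
    deadline = time.monotonic() + timeout
    try:
        while True:
            try:
                fcntl.flock(fh.fileno(), fcntl.LOCK_EX | fcntl.LOCK_NB)
                break
            except BlockingIOError:
                if time.monotonic() >= deadline:
                    raise LockTimeoutError(
                        f"could not lock {lock_path} within {timeout} s"
                    ) from None
                time.sleep(0.05)
        yield
    finally:
        fcntl.flock(fh.fileno(), fcntl.LOCK_UN)
        fh.close()


@dataclass(frozen=True)
class AllocationResult:
    """Everything produced by one allocation transaction."""

    record: core.AllocationRecord
    decision: core.AllocationDecision
    counts: TrialCounts
    arm_label: str
    state_line: str
    messages: tuple[Message, ...]


class MinimisationEngine:
    """Covariate-adaptive allocation engine for one two-arm trial.

    Owns the single seedable random generator used for every coin draw; a
    fixed config seed makes an entire submission stream reproducible.
    """

    def __init__(
        self,
        config: EngineConfig,
        transport: Transport | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.config = config
        self.transport = transport if transport is not None else FileTransport(config.outbox_path)
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)

    # -- intake ------------------------------------------------------------

    def submit(self, raw, now: _dt.datetime | None = None) -> ParticipantSubmission:
        """Validate raw fields against this trial's scheme and vocabularies."""
        return stamp_submission(
            raw,
            scheme=self.config.scheme,
            vocabulary=self.config.vocabulary,
            age_threshold=self.config.age_threshold,
            now=now,
        )

    # -- the transaction ---------------------------------------------------

    def allocate(
        self,
        submission: ParticipantSubmission,
        allow_duplicate: bool = False,
        notify: bool = True,
        lock_timeout: float = 10.0,
    ) -> AllocationResult:
        """Allocate one participant: load -> decide -> append -> notify.

        Runs under the exclusive state-file lock. The participant ID must
        not already appear in the history unless ``allow_duplicate`` is set.
        Notification failures are logged but never roll back the allocation.
        """
        cfg = self.config
        with exclusive_lock(cfg.state_path, timeout=lock_timeout):
            records = state.load_history(cfg.state_path, cfg.scheme, cfg.delimiter)
            if not allow_duplicate:
                for r in records:
                    if r.participant_id == submission.participant_id:
                        raise DuplicateParticipantError(
                            f"participant {submission.participant_id!r} is already "
                            "allocated; pass allow_duplicate to override"
                        )
            vector = core.make_class_vector(submission, cfg.scheme)
            control, experimental = core.aggregate_history(records, cfg.scheme)
            decision = core.decide_allocation(
                vector, control, experimental, cfg.randomisation_element, self.rng
            )
            record = core.finalize_record(submission, vector, decision, cfg.scheme)
            line = state.append_record(
                record, cfg.scheme, cfg.state_path, cfg.archive_path, cfg.delimiter
            )
            counts = TrialCounts(
                total=len(records) + 1,
                control=control.count + (1 if decision.arm == OPTION1 else 0),
                experimental=experimental.count + (0 if decision.arm == OPTION1 else 1),
            )
            history_text = cfg.state_path.read_text(encoding="utf-8")

        messages: tuple[Message, ...] = ()
        if notify:
            report: NotificationReport = dispatch_notifications(
                record,
                counts,
                history_text,
                cfg.scheme,
                cfg.randomisation_element,
                nurse=cfg.recipients.nurse,
                admin=cfg.recipients.admin,
                extra_recipients=cfg.recipients.extra,
                transport=self.transport,
                trial_name=cfg.trial_name,
                delimiter=cfg.delimiter,
            )
            messages = report.messages
            for failure in report.failures:
                logger.warning("notification delivery failed: %s", failure)

        return AllocationResult(
            record=record,
            decision=decision,
            counts=counts,
            arm_label=cfg.scheme.arm_label(decision.arm),
            state_line=line,
            messages=messages,
        )

    # -- inspection --------------------------------------------------------

    def status(self) -> tuple[TrialCounts, core.ArmAggregate, core.ArmAggregate]:
        """Current counts and per-arm marginal totals from the state file."""
        cfg = self.config
        records = state.load_history(cfg.state_path, cfg.scheme, cfg.delimiter)
        control, experimental = core.aggregate_history(records, cfg.scheme)
        counts = TrialCounts(len(records), control.count, experimental.count)
        return counts, control, experimental
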
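"""Durable allocation state: the delimited text file and its backups.

The single source of truth for a trial is a plain-text state file with one
line per allocated participant. Fields are joined by a configurable
delimiter (default ``zz``) in a fixed order: participant ID, date, weekday,
submitter, then every class value including the two outcome positions.
Every successful allocation appends the identical line to a mirrored
archive file, and the full file content is embedded in each administrator
notification between marker lines, from which the state file can be rebuilt
byte-identically.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np

from .core import AllocationRecord, ClassVector
from .errors import CorruptHistoryError, ReconstructionError, SerializationError
from .scheme import FactorScheme

DEFAULT_DELIMITER = "zz"
N_DOCUMENTARY_FIELDS = 4  # participant ID, date, weekday, submitter

BACKUP_BEGIN = "=== BEGIN ALLOCATION STATE FILE ==="
BACKUP_END = "=== END ALLOCATION STATE FILE ==="


def _format_value(v: float) -> str:
    """Render a class value compactly but losslessly (1 -> "1", 0.5 -> "0.5")."""
    return str(int(v)) if float(v) == int(v) else repr(float(v))


def format_line(
    record: AllocationRecord,
    scheme: FactorScheme,
    delimiter: str = DEFAULT_DELIMITER,
) -> str:
    """Serialize one record as a single delimited line (no trailing newline)."""
    documentary = {
        "participant_id": record.participant_id,
        "date": record.date,
        "weekday": record.weekday,
        "submitter": record.submitter,
    }
    for name, value in documentary.items():
        if delimiter in value:
            raise SerializationError(
                f"field {name!r} contains the delimiter {delimiter!r}: {value!r}; "
                "reject the value at intake or configure a different delimiter"
            )
        if "\n" in value or "\r" in value:
            raise SerializationError(f"field {name!r} contains a newline: {value!r}")
    if len(record.vector.values) != scheme.vector_length:
        raise SerializationError(
            f"vector length {len(record.vector.values)} != scheme length {scheme.vector_length}"
        )
    fields = list(documentary.values()) + [_format_value(v) for v in record.vector.values]
    line = delimiter.join(fields)
    # Joining can be ambiguous even when no field contains the delimiter
    # (e.g. a field ending in "z" next to the "zz" divider); refuse any line
    # that would not split back into the original fields.
    if line.split(delimiter) != fields:
        raise SerializationError(
            f"fields are ambiguous under delimiter {delimiter!r} "
            "(a field boundary forms the delimiter); adjust the value at "
            "intake or configure a different delimiter"
        )
    return line


def parse_line(
    line: str,
    scheme: FactorScheme,
    delimiter: str = DEFAULT_DELIMITER,
    line_no: int | None = None,
) -> AllocationRecord:
    """Parse one state-file line back into an AllocationRecord.

    Rejects lines with the wrong field count, non-numeric class values,
    anything but exactly one outcome flag, or more or fewer than one nonzero
    value per factor.
    """
    parts = line.split(delimiter)
    expected = N_DOCUMENTARY_FIELDS + scheme.vector_length
    if len(parts) != expected:
        raise CorruptHistoryError(
            f"expected {expected} fields, got {len(parts)}", line_no=line_no
        )
    try:
        values = np.array([float(p) for p in parts[N_DOCUMENTARY_FIELDS:]])
    except ValueError:
        raise CorruptHistoryError(
            f"non-numeric class value in {parts[N_DOCUMENTARY_FIELDS:]!r}", line_no=line_no
        ) from None
    outcome_flags = values[-2:] != 0
    if outcome_flags.sum() != 1:
        raise CorruptHistoryError(
            f"{int(outcome_flags.sum())} outcome flags set (expected exactly 1)",
            line_no=line_no,
        )
    for factor in scheme.factors:
        pos = scheme.positions_of(factor.name)
        nonzero = np.count_nonzero(values[pos.start : pos.stop])
        if nonzero != 1:
            raise CorruptHistoryError(
                f"factor {factor.name!r} has {nonzero} nonzero classes (expected exactly 1)",
                line_no=line_no,
            )
    pid, date, weekday, submitter = parts[:N_DOCUMENTARY_FIELDS]
    return AllocationRecord(
        participant_id=pid,
        date=date,
        weekday=weekday,
        submitter=submitter,
        vector=ClassVector(values),
    )


def load_history(
    path: str | Path,
    scheme: FactorScheme,
    delimiter: str = DEFAULT_DELIMITER,
) -> list[AllocationRecord]:
    """Read all allocation records from a state file.

    A missing file is an empty trial. Blank lines are skipped with a
    warning; any malformed line aborts the load with its line number.
    """
    path = Path(path)
    if not path.exists():
        return []
    records = []
    with path.open("r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                warnings.warn(f"{path}: skipping blank line {line_no}", stacklevel=2)
                continue
            records.append(parse_line(stripped, scheme, delimiter, line_no=line_no))
    return records


def append_record(
    record: AllocationRecord,
    scheme: FactorScheme,
    state_path: str | Path,
    archive_path: str | Path,
    delimiter: str = DEFAULT_DELIMITER,
) -> str:
    """Append one record to the state file and its mirrored archive.

    The line is fully serialized (and can fail) before anything is written,
    so a serialization error leaves both files untouched. A missing archive
    file mid-trial is recreated with a warning — the state file is the
    source of truth, the archive a redundant mirror.
    """
    line = format_line(record, scheme, delimiter)
    state_path, archive_path = Path(state_path), Path(archive_path)
    if state_path.exists() and state_path.stat().st_size > 0 and not archive_path.exists():
        warnings.warn(f"archive file {archive_path} was missing; recreating", stacklevel=2)
    with state_path.open("a", encoding="utf-8") as fh:
        fh.write(line + "\n")
        fh.flush()
        os.fsync(fh.fileno())
    with archive_path.open("a", encoding="utf-8") as fh:
        fh.write(line + "\n")
    return line


def write_state_file(
    records,
    path: str | Path,
    scheme: FactorScheme,
    delimiter: str = DEFAULT_DELIMITER,
) -> None:
    """Write a complete state file from scratch (simulator / rebuild)."""
    content = "".join(format_line(r, scheme, delimiter) + "\n" for r in records)
    Path(path).write_text(content, encoding="utf-8")


def rebuild_from_backup(backup_text: str) -> str:
    """Recover the state-file content embedded in an administrator message.

    Returns the text between the backup markers, byte-identical to the
    state file at the moment the message was composed. An empty trial yields
    empty content.
    """
    begin = backup_text.find(BACKUP_BEGIN + "\n")
    if begin < 0:
        raise ReconstructionError(
            f"no state-file block found (missing marker {BACKUP_BEGIN!r})"
        )
    start = begin + len(BACKUP_BEGIN) + 1
    end = backup_text.find(BACKUP_END, start)
    if end < 0:
        raise ReconstructionError(
            f"state-file block is not terminated (missing marker {BACKUP_END!r})"
        )
    if end > start and backup_text[end - 1] != "\n":
        raise ReconstructionError("state-file block is malformed (end marker mid-line)")
    return backup_text[start:end]
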
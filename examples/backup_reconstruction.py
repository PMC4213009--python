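"""Rebuilding a trial from its administrator notification.

Every allocation embeds the full state file in the administrator message,
so the trial survives total loss of the server's files. This example runs
a 10-participant simulated trial through the engine, deletes the state
file, and reconstructs it byte-identically from the last admin message.
"""

import tempfile
from pathlib import Path

from trialminim import (
    EngineConfig,
    MinimisationEngine,
    RecordingTransport,
    default_population_model,
    generate_stream,
    rebuild_from_backup,
)

workdir = Path(tempfile.mkdtemp(prefix="trial-backup-"))
config = EngineConfig(
    seed=7,
    state_path=workdir / "state.txt",
    archive_path=workdir / "archive.txt",
    outbox_path=workdir / "outbox",
)
engine = MinimisationEngine(config, transport=RecordingTransport())

for submission in generate_stream(default_population_model(n=10, seed=3)):
    result = engine.allocate(submission)

original = config.state_path.read_text()
admin_message = result.messages[2]  # submitter, nurse, administrator
print(f"trial has {len(original.splitlines())} allocations on disk")
print(f"admin message subject: {admin_message.subject}")

config.state_path.unlink()
print("state file deleted ...")

restored = rebuild_from_backup(admin_message.body)
config.state_path.write_text(restored)
print(f"restored from the admin message: byte-identical = {restored == original}")
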
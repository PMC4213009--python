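# trialminim

Covariate-adaptive **minimization** for two-arm clinical trials: a Python
library and thin command-line tool that allocates participants between a
control and an experimental arm while keeping prognostic factors (gender,
age class, diabetes status, ethnicity, ...) balanced across the arms — the
problem that simple randomization handles poorly in small studies.

It is written for trial teams that need auditable, real-time allocation
without database infrastructure: the entire state of a trial is one
append-only delimited text file, mirrored to an archive and embedded in
every administrator notification, from which the whole study can be
reconstructed byte-for-byte.

## The algorithm

Each participant is encoded as a **class vector**: one position per factor
level (10 allocation classes in the default scheme: male/female,
young/old, diabetes no/yes, and four aggregated ethnicity categories) plus
two terminal outcome positions for the assigned arm. Exactly one position
per factor is nonzero and holds that level's weight *w* (1 by default;
lowering a factor's weights makes it count proportionally less).

The history of a trial is summarised by two **arm aggregates** — the
elementwise sums (marginal totals) of the class vectors already allocated
to each arm. A new participant's score against an arm is

&nbsp;&nbsp;&nbsp;&nbsp;*S*(arm) = Σ<sub>k ∈ matched classes</sub> *T*<sub>arm,k</sub>

the sum of that arm's totals at the participant's own (nonzero) classes.
Three scenarios follow:

* *S*(control) = *S*(experimental): allocate at random (p = ½) — the first
  participant of every trial is therefore always randomized;
* *S*(experimental) > *S*(control): the control arm is preferred — the
  participant's characteristics are scarcer there;
* *S*(control) > *S*(experimental): the experimental arm is preferred.

The preferred arm is followed with probability **r**, the *randomization
element*: r = 1 is deterministic minimization, r = 0.8 allows a 20%
random departure (allocation concealment), and r = 0.5 is pure
randomization. Values below 0.5 would systematically oppose minimization
and are rejected.

## Worked example

```python
import numpy as np
from trialminim import (ArmAggregate, arm_scores, decide_allocation,
                        default_scheme)

scheme = default_scheme()
# a male, young, non-diabetic, white participant; the arm totals at those
# four matched classes are (25, 26, 14, 30) and (23, 22, 18, 35)
```

Running `python examples/worked_score_example.py` prints:

```
control score:      95   (25 + 26 + 14 + 30)
experimental score: 98   (23 + 22 + 18 + 35)
decision: Control Arm (deterministic)
```

The participant's characteristics are less represented in the control arm,
so minimization allocates them there. `examples/` contains three more
narrative scripts: a full allocation transaction with the 18-line
notification and 'zz'-delimited state file (`allocate_participants.py`),
byte-identical reconstruction of a deleted state file from an
administrator message (`backup_reconstruction.py`), and a paired
simulation showing what minimization buys (`balance_comparison.py`):

```
   r  mean_max_imbalance  mean_arm_size_diff
1.00                1.56                0.28
0.80                2.58                0.90
0.50               13.81               10.14
```

— over 100 simulated 152-participant trials, deterministic minimization
keeps the worst per-class count difference between arms near 1–2 where
pure randomization averages ~14.

## Command line

```sh
trialminim init --config trial.yml            # scaffold config + empty state
trialminim allocate --config trial.yml \
    --id P001 --gender female --age 64 --diabetes no \
    --ethnicity-code A --submitter nurse@example.org
trialminim status --config trial.yml
trialminim simulate --n 152 --replicates 200 --r 1.0 --r 0.5 --seed 1
trialminim rebuild backup_message.txt --config trial.yml
trialminim export --config trial.yml --out history.csv
```

`allocate` shows a confirmation summary before anything is persisted
(`--yes` skips it), exits 2 on validation failure with nothing written,
and composes three notifications per allocation (submitter, study nurse,
administrator) into the configured outbox directory.

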
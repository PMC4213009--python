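"""The minimization score, worked by hand.

Builds arm aggregates whose marginal totals at a new participant's matched
classes (male, young, non-diabetic, white) are 25, 26, 14, 30 for the
control arm and 23, 22, 18, 35 for the experimental arm, then scores and
decides the allocation under deterministic minimization (r = 1).
"""

import datetime as dt

import numpy as np

from trialminim import (
    ArmAggregate,
    ParticipantSubmission,
    arm_scores,
    decide_allocation,
    default_scheme,
    make_class_vector,
)

scheme = default_scheme()

participant = ParticipantSubmission(
    participant_id="NEW-001", submitter_email="researcher@example.org",
    gender="male", age_years=40, diabetes="no",
    ethnicity_code="A", ethnicity="white", age_class="young",
    timestamp=dt.datetime(2014, 10, 29, 9, 0),
    levels={"gender": "male", "age_class": "young",
            "diabetes": "no", "ethnicity": "white"},
)
vector = make_class_vector(participant, scheme)

matched = [scheme.index_of("gender", "male"),
           scheme.index_of("age_class", "young"),
           scheme.index_of("diabetes", "no"),
           scheme.index_of("ethnicity", "white")]
control_totals = np.zeros(scheme.n_classes)
experimental_totals = np.zeros(scheme.n_classes)
control_totals[matched] = [25, 26, 14, 30]
experimental_totals[matched] = [23, 22, 18, 35]
control = ArmAggregate(control_totals, count=51)
experimental = ArmAggregate(experimental_totals, count=50)

cs, es = arm_scores(vector, control, experimental)
print(f"control score:      {cs:g}   (25 + 26 + 14 + 30)")
print(f"experimental score: {es:g}   (23 + 22 + 18 + 35)")

decision = decide_allocation(vector, control, experimental, r=1.0,
                             rng=np.random.default_rng(0))
print(f"decision: {scheme.arm_label(decision.arm)} ({decision.mode})")
print()
print("The participant's characteristics are scarcer in the control arm")
print("(lower score), so minimization sends them there; with r = 1 the")
print("decision is deterministic and no random draw is consumed.")
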
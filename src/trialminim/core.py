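"""Minimization core: class vectors, arm aggregates, scores and decisions.

The allocation model. Each participant is described by a *class vector*: one
position per factor level (10 allocation classes under the default scheme)
plus two terminal outcome positions recording the assigned arm. Exactly one
position per factor is nonzero and holds that level's weight (1 by default).

The accumulated history of a trial is summarised by two *arm aggregates* —
elementwise sums of the class vectors of all participants already in the
control and experimental arms (the marginal totals). A new participant's
minimization score against an arm is the sum of that arm's totals at the
positions where the participant's own allocation classes are nonzero. The
participant is steered toward the arm with the *lower* score, i.e. the arm
in which their characteristics are currently under-represented, softened by
a biased coin with probability r (the randomization element) of following
the preferred arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    CorruptHistoryError,
    DoubleAllocationError,
    SchemeMismatchError,
    ValidationError,
)
from .intake import ParticipantSubmission
from .scheme import OPTION1, OPTION2, FactorScheme

MODE_TIE_RANDOM = "tie_random"
MODE_DETERMINISTIC = "deterministic"
MODE_BIASED_COIN = "biased_coin"


@dataclass
class ClassVector:
    """A participant's values over all allocation classes plus two outcomes."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def is_finalized(self) -> bool:
        return bool(np.any(self.values[-2:] != 0))

    def copy(self) -> "ClassVector":
        return ClassVector(self.values.copy())

    def __eq__(self, other):
        return isinstance(other, ClassVector) and np.array_equal(self.values, other.values)


@dataclass
class ArmAggregate:
    """Marginal totals for one arm: elementwise sum of its class vectors."""

    totals: np.ndarray
    count: int = 0

    def __post_init__(self):
        self.totals = np.asarray(self.totals, dtype=float)

    @classmethod
    def empty(cls, scheme: FactorScheme) -> "ArmAggregate":
        return cls(np.zeros(scheme.n_classes), 0)

    def add(self, vector: ClassVector) -> None:
        """Fold one participant's allocation classes into the totals."""
        self.totals += vector.values[: len(self.totals)]
        self.count += 1


@dataclass(frozen=True)
class AllocationDecision:
    """Outcome of the minimization step for one participant.

    ``coin_draw`` is the uniform variate consumed, kept for the audit trail;
    it is absent exactly when no randomness was used (r = 1 with unequal
    scores).
    """

    arm: str
    control_score: float
    experimental_score: float
    mode: str
    coin_draw: float | None = None


@dataclass
class AllocationRecord:
    """One finalized participant: documentary fields plus a finalized vector."""

    participant_id: str
    date: str
    weekday: str
    submitter: str
    vector: ClassVector
    submission: ParticipantSubmission | None = field(default=None, compare=False)

    @property
    def arm(self) -> str:
        v = self.vector.values
        return OPTION1 if v[-2] != 0 else OPTION2


def make_class_vector(submission: ParticipantSubmission, scheme: FactorScheme) -> ClassVector:
    """Encode a submission as a class vector under the scheme.

    Every factor contributes its configured weight at the participant's true
    level and 0 elsewhere; both outcome positions start at 0.
    """
    values = np.zeros(scheme.vector_length)
    problems = []
    for factor in scheme.factors:
        level = submission.levels.get(factor.name)
        if level is None or level not in factor.levels:
            problems.append(
                f"{factor.name}: unknown level {level!r} "
                f"(expected one of {', '.join(factor.levels)})"
            )
            continue
        values[scheme.index_of(factor.name, level)] = factor.weight_of(level)
    if problems:
        raise ValidationError(problems)
    return ClassVector(values)


def aggregate_history(
    records, scheme: FactorScheme
) -> tuple[ArmAggregate, ArmAggregate]:
    """Fold prior allocation records into per-arm marginal totals.

    Returns (control, experimental). Each record must carry exactly one
    outcome flag; anything else indicates a corrupted history line.
    """
    control = ArmAggregate.empty(scheme)
    experimental = ArmAggregate.empty(scheme)
    for idx, record in enumerate(records):
        v = record.vector.values
        if len(v) != scheme.vector_length:
            raise SchemeMismatchError(
                f"record {idx}: vector length {len(v)} != scheme length {scheme.vector_length}"
            )
        flags = v[-2:] != 0
        if flags.sum() != 1:
            raise CorruptHistoryError(
                f"record has {int(flags.sum())} outcome flags set (expected exactly 1)",
                line_no=idx,
            )
        (control if flags[0] else experimental).add(record.vector)
    return control, experimental


def arm_scores(
    vector: ClassVector, control: ArmAggregate, experimental: ArmAggregate
) -> tuple[float, float]:
    """Minimization scores: each arm's totals summed at the matched classes.

    A class is matched when the new participant's value there is nonzero.
    With unit weights this is the dot product of the participant's 0/1
    indicator with each arm's marginal totals.
    """
    n = len(control.totals)
    if len(experimental.totals) != n or len(vector.values) != n + 2:
        raise SchemeMismatchError(
            f"length mismatch: vector {len(vector.values)}, "
            f"control {len(control.totals)}, experimental {len(experimental.totals)}"
        )
    matched = vector.values[:n] != 0
    return float(control.totals[matched].sum()), float(experimental.totals[matched].sum())


def randomise_arm(p_option1: float, rng: np.random.Generator) -> tuple[str, float]:
    """Biased-coin draw: option 1 iff a uniform draw falls below p_option1.

    Returns the chosen arm together with the drawn uniform value, which is
    retained in the decision record for the audit trail.
    """
    if not 0.0 <= p_option1 <= 1.0:
        raise ValidationError(f"p_option1: probability must be in [0, 1], got {p_option1}")
    draw = float(rng.random())
    return (OPTION1 if draw < p_option1 else OPTION2), draw


def decide_allocation(
    vector: ClassVector,
    control: ArmAggregate,
    experimental: ArmAggregate,
    r: float,
    rng: np.random.Generator,
) -> AllocationDecision:
    """Decide the arm for a new participant by score minimization.

    Three scenarios:

    * equal scores — allocate at random (probability 0.5 per arm), so the
      first participant of any trial is always randomized;
    * experimental score greater — control is preferred; follow it with
      probability r;
    * control score greater — experimental is preferred; follow it with
      probability r (equivalently, choose control with probability 1 - r).

    r must lie in [0.5, 1]: r = 1 is deterministic minimization, r = 0.5 is
    pure randomization. When r = 1 and the scores differ no random draw is
    consumed, so the decision is a pure function of its inputs.
    """
    if not 0.5 <= r <= 1.0:
        raise ConfigurationError(
            f"randomization element must be in [0.5, 1], got {r}: r is the "
            "probability of following the minimization-preferred arm "
            "(1 = deterministic minimization, 0.5 = pure randomization); "
            "values below 0.5 would systematically oppose minimization"
        )
    cs, es = arm_scores(vector, control, experimental)
    if cs == es:
        arm, draw = randomise_arm(0.5, rng)
        return AllocationDecision(arm, cs, es, MODE_TIE_RANDOM, draw)
    p_control = r if es > cs else 1.0 - r
    if r == 1.0:
        arm = OPTION1 if es > cs else OPTION2
        return AllocationDecision(arm, cs, es, MODE_DETERMINISTIC, None)
    arm, draw = randomise_arm(p_control, rng)
    return AllocationDecision(arm, cs, es, MODE_BIASED_COIN, draw)


def finalize_record(
    submission: ParticipantSubmission,
    vector: ClassVector,
    decision: AllocationDecision,
    scheme: FactorScheme,
) -> AllocationRecord:
    """Stamp the decided arm into the vector and build the durable record."""
    if vector.is_finalized:
        raise DoubleAllocationError(
            f"participant {submission.participant_id!r}: vector already carries an outcome"
        )
    final = vector.copy()
    final.values[scheme.option1_pos if decision.arm == OPTION1 else scheme.option2_pos] = 1.0
    return AllocationRecord(
        participant_id=submission.participant_id,
        date=submission.date,
        weekday=submission.weekday,
        submitter=submission.submitter_email,
        vector=final,
        submission=submission,
    )
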
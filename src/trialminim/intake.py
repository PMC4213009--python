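"""Intake: turn raw form/CLI fields into a validated participant submission.

The intake layer performs the distillation step that in a web deployment
would live in the entry form: the detailed 17-code ethnicity vocabulary is
aggregated down to 4 generic categories, age in years is cut at a threshold
(default 65) into a binary age class, and the submission is stamped with the
ISO date and weekday name. All validation problems are collected and
reported together.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ValidationError
from .scheme import FactorScheme

MAX_AGE = 150
DEFAULT_AGE_THRESHOLD = 65

#: Synthetic default detailed-ethnicity vocabulary (a stand-in): 17 detailed
#: codes modeled on the UK NHS/census ethnicity code letters, mapped onto
#: exactly four aggregated categories. Codes A, B and C (White: British,
#: Irish, any other White background) aggregate to "white". The full
#: assignment is trial configuration data and can be overridden per study.
DEFAULT_ETHNICITY_CODES: dict[str, str] = {
    "A": "white",    # White: British
    "B": "white",    # White: Irish
    "C": "white",    # White: any other White background
    "D": "black",    # Mixed: White and Black Caribbean
    "E": "black",    # Mixed: White and Black African
    "F": "asian",    # Mixed: White and Asian
    "G": "white",    # Mixed: any other Mixed background
    "H": "asian",    # Asian or Asian British: Indian
    "J": "asian",    # Asian or Asian British: Pakistani
    "K": "asian",    # Asian or Asian British: Bangladeshi
    "L": "asian",    # Asian or Asian British: any other Asian background
    "M": "black",    # Black or Black British: Caribbean
    "N": "black",    # Black or Black British: African
    "P": "black",    # Black or Black British: any other Black background
    "R": "chinese",  # Chinese
    "S": "white",    # Any other ethnic group
    "Z": "white",    # Not stated
}


@dataclass(frozen=True)
class EthnicityVocabulary:
    """Mapping from detailed intake codes to aggregated categories.

    Invariants enforced at construction: exactly 17 detailed codes, exactly
    4 distinct aggregated categories, and codes A, B, C all aggregate to
    "white".
    """

    codes: Mapping[str, str]

    def __post_init__(self):
        codes = dict(self.codes)
        object.__setattr__(self, "codes", codes)
        problems = []
        if len(codes) != 17:
            problems.append(f"vocabulary must have exactly 17 detailed codes, got {len(codes)}")
        categories = set(codes.values())
        if len(categories) != 4:
            problems.append(
                f"vocabulary must aggregate onto exactly 4 categories, got {sorted(categories)}"
            )
        for c in ("A", "B", "C"):
            if codes.get(c) != "white":
                problems.append(f"code {c} must aggregate to 'white', got {codes.get(c)!r}")
        if problems:
            raise ValidationError(problems)

    @property
    def categories(self) -> tuple[str, ...]:
        """Aggregated categories in first-appearance order."""
        seen = []
        for cat in self.codes.values():
            if cat not in seen:
                seen.append(cat)
        return tuple(seen)

    def codes_for(self, category: str) -> tuple[str, ...]:
        return tuple(c for c, cat in self.codes.items() if cat == category)


def default_vocabulary() -> EthnicityVocabulary:
    return EthnicityVocabulary(DEFAULT_ETHNICITY_CODES)


def aggregate_ethnicity(code: str, vocab: EthnicityVocabulary) -> str:
    """Aggregate a detailed ethnicity code to one of the 4 generic categories."""
    try:
        return vocab.codes[code]
    except KeyError:
        legal = ", ".join(sorted(vocab.codes))
        raise ValidationError(
            f"ethnicity_code: unknown code {code!r} (legal codes: {legal})"
        ) from None


def derive_age_class(age_years: int, threshold: int = DEFAULT_AGE_THRESHOLD) -> str:
    """Binary age class: below the threshold is "young", at or above is "old".

    The boundary is inclusive on the old side: at the default threshold of
    65, a 65-year-old falls in the "old" (>=65) class.
    """
    age = int(age_years)
    if age < 0 or age > MAX_AGE:
        raise ValidationError(f"age_years: must be between 0 and {MAX_AGE}, got {age}")
    return "old" if age >= threshold else "young"


@dataclass(frozen=True)
class ParticipantSubmission:
    """A validated, stamped participant ready for allocation.

    ``levels`` maps every scheme factor name to this participant's level and
    is the only part the minimization core reads; the remaining fields are
    documentary (they appear in notifications and the state file but play no
    role in the allocation decision).
    """

    participant_id: str
    submitter_email: str
    gender: str
    age_years: int
    diabetes: str
    ethnicity_code: str
    ethnicity: str
    age_class: str
    timestamp: _dt.datetime
    levels: Mapping[str, str] = field(compare=False)

    @property
    def date(self) -> str:
        return self.timestamp.date().isoformat()

    @property
    def weekday(self) -> str:
        return self.timestamp.strftime("%A")

    @property
    def time(self) -> str:
        return self.timestamp.strftime("%H:%M:%S")


def stamp_submission(
    raw: Mapping[str, object],
    scheme: FactorScheme,
    vocabulary: EthnicityVocabulary | None = None,
    age_threshold: int = DEFAULT_AGE_THRESHOLD,
    now: _dt.datetime | None = None,
) -> ParticipantSubmission:
    """Validate raw fields and stamp them into a ParticipantSubmission.

    All problems are gathered and raised together in one ValidationError so
    a submitter can fix everything in a single pass. ``now`` injects a clock
    for reproducible stamping.

    Required keys in ``raw``: participant_id, submitter_email (or submitter),
    gender, age_years (or age), diabetes, ethnicity_code. Any additional
    scheme factor beyond the shipped four is looked up in ``raw`` by its
    factor name.
    """
    vocabulary = vocabulary or default_vocabulary()
    problems: list[str] = []

    pid = str(raw.get("participant_id") or "").strip()
    if not pid:
        problems.append("participant_id: required")
    submitter = str(raw.get("submitter_email") or raw.get("submitter") or "").strip()
    if not submitter:
        problems.append("submitter_email: required")

    age_raw = raw.get("age_years", raw.get("age"))
    age, age_class = -1, ""
    if age_raw is None or str(age_raw).strip() == "":
        problems.append("age_years: required")
    else:
        try:
            age = int(str(age_raw).strip())
            age_class = derive_age_class(age, age_threshold)
        except ValidationError as exc:
            problems.extend(exc.problems)
        except ValueError:
            problems.append(f"age_years: not an integer: {age_raw!r}")

    code = str(raw.get("ethnicity_code") or "").strip()
    ethnicity = ""
    if not code:
        problems.append("ethnicity_code: required")
    else:
        try:
            ethnicity = aggregate_ethnicity(code, vocabulary)
        except ValidationError as exc:
            problems.extend(exc.problems)

    derived = {"age_class": age_class, "ethnicity": ethnicity}
    levels: dict[str, str] = {}
    for factor in scheme.factors:
        value = derived.get(factor.name)
        if value is None:
            value = str(raw.get(factor.name) or "").strip()
            if not value:
                problems.append(f"{factor.name}: required")
                continue
            if value not in factor.levels:
                problems.append(
                    f"{factor.name}: unknown level {value!r} "
                    f"(expected one of {', '.join(factor.levels)})"
                )
                continue
        elif value == "":
            continue  # already reported above
        levels[factor.name] = value

    if problems:
        raise ValidationError(problems)

    timestamp = now or _dt.datetime.now()
    return ParticipantSubmission(
        participant_id=pid,
        submitter_email=submitter,
        gender=levels.get("gender", str(raw.get("gender", ""))),
        age_years=age,
        diabetes=levels.get("diabetes", str(raw.get("diabetes", ""))),
        ethnicity_code=code,
        ethnicity=ethnicity,
        age_class=age_class,
        timestamp=timestamp,
        levels=levels,
    )


def confirmation_summary(submission: ParticipantSubmission) -> str:
    """The check-your-input summary shown before allocation proceeds.

    Mirrors the two-step confirm flow: the caller displays this summary and
    only proceeds to allocation once the submitter confirms it is correct.
    """
    return "\n".join(
        [
            "Please confirm the submitted details:",
            f"  Participant ID:       {submission.participant_id}",
            f"  Date:                 {submission.date}",
            f"  Weekday:              {submission.weekday}",
            f"  Submitted by:         {submission.submitter_email}",
            f"  Gender:               {submission.gender}",
            f"  Age:                  {submission.age_years} ({submission.age_class})",
            f"  Diabetes:             {submission.diabetes}",
            f"  Ethnicity code:       {submission.ethnicity_code} ({submission.ethnicity})",
        ]
    )
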
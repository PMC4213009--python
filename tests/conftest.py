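"""Shared fixtures: schemes, submissions, hand-built records, trial dirs."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from trialminim import (
    ClassVector,
    EngineConfig,
    MinimisationEngine,
    ParticipantSubmission,
    RecordingTransport,
    default_scheme,
)
from trialminim.core import AllocationRecord

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

FIXED_NOW = dt.datetime(2014, 10, 29, 12, 30, 0)


@pytest.fixture
def scheme():
    return default_scheme()


def build_submission(
    participant_id="P001",
    gender="female",
    age_years=52,
    diabetes="no",
    ethnicity_code="A",
    ethnicity="white",
    submitter="researcher@example.org",
    timestamp=FIXED_NOW,
):
    age_class = "old" if age_years >= 65 else "young"
    return ParticipantSubmission(
        participant_id=participant_id,
        submitter_email=submitter,
        gender=gender,
        age_years=age_years,
        diabetes=diabetes,
        ethnicity_code=ethnicity_code,
        ethnicity=ethnicity,
        age_class=age_class,
        timestamp=timestamp,
        levels={
            "gender": gender,
            "age_class": age_class,
            "diabetes": diabetes,
            "ethnicity": ethnicity,
        },
    )


@pytest.fixture
def submission():
    return build_submission()


def build_record(scheme, levels, arm="option1", participant_id="R1",
                 date="2014-10-29", weekday="Wednesday", submitter="s@x.org"):
    """Hand-build a finalized record from a {factor: level} mapping."""
    values = np.zeros(scheme.vector_length)
    for factor in scheme.factors:
        values[scheme.index_of(factor.name, levels[factor.name])] = factor.weight_of(
            levels[factor.name]
        )
    values[scheme.option1_pos if arm == "option1" else scheme.option2_pos] = 1.0
    return AllocationRecord(
        participant_id=participant_id,
        date=date,
        weekday=weekday,
        submitter=submitter,
        vector=ClassVector(values),
    )


@pytest.fixture
def trial(tmp_path):
    """A fresh trial: seeded engine with recording transport in tmp_path."""
    cfg = EngineConfig(
        seed=42,
        state_path=tmp_path / "state.txt",
        archive_path=tmp_path / "archive.txt",
        outbox_path=tmp_path / "outbox",
    )
    return MinimisationEngine(cfg, transport=RecordingTransport())
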
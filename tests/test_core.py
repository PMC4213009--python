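"""Unit tests for class vectors, aggregation, scores and decisions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trialminim import (
    ArmAggregate,
    ClassVector,
    ConfigurationError,
    CorruptHistoryError,
    DoubleAllocationError,
    Factor,
    FactorScheme,
    OPTION1,
    OPTION2,
    SchemeMismatchError,
    ValidationError,
    aggregate_history,
    arm_scores,
    decide_allocation,
    default_scheme,
    finalize_record,
    make_class_vector,
    randomise_arm,
)
from trialminim.core import MODE_BIASED_COIN, MODE_DETERMINISTIC, MODE_TIE_RANDOM

from conftest import build_record, build_submission


# ---------------------------------------------------------------- scheme

def test_default_scheme_has_ten_allocation_classes(scheme):
    assert scheme.n_classes == 10
    assert scheme.vector_length == 12
    assert scheme.class_labels[0] == ("gender", "male")
    assert scheme.option1_pos == 10 and scheme.option2_pos == 11


def test_scheme_rejects_degenerate_factors():
    with pytest.raises(ConfigurationError):
        Factor("gender", ("male",))
    with pytest.raises(ConfigurationError):
        Factor("gender", ("male", "male"))
    with pytest.raises(ConfigurationError):
        Factor("gender", ("male", "female"), (1.0, -0.5))
    with pytest.raises(ConfigurationError):
        FactorScheme((Factor("a", ("x", "y")), Factor("a", ("p", "q"))))


# ---------------------------------------------------------- class vectors

def test_female_participant_sets_female_one_male_zero(scheme):
    v = make_class_vector(build_submission(gender="female"), scheme)
    assert v.values[scheme.index_of("gender", "male")] == 0
    assert v.values[scheme.index_of("gender", "female")] == 1
    assert not v.is_finalized


def test_outcome_positions_start_at_zero(scheme):
    v = make_class_vector(build_submission(), scheme)
    assert v.values[-2] == 0 and v.values[-1] == 0


@given(
    gender=st.sampled_from(["male", "female"]),
    age=st.integers(0, 150),
    diabetes=st.sampled_from(["no", "yes"]),
    ethnicity=st.sampled_from(["white", "black", "asian", "chinese"]),
)
def test_exactly_one_nonzero_class_per_factor(gender, age, diabetes, ethnicity):
    scheme = default_scheme()
    sub = build_submission(gender=gender, age_years=age, diabetes=diabetes,
                           ethnicity=ethnicity)
    v = make_class_vector(sub, scheme)
    for factor in scheme.factors:
        pos = scheme.positions_of(factor.name)
        assert np.count_nonzero(v.values[pos.start:pos.stop]) == 1


def test_half_weighted_ethnicity_contributes_half():
    scheme = FactorScheme((
        Factor("gender", ("male", "female")),
        Factor("ethnicity", ("white", "black", "asian", "chinese"),
               (0.5, 0.5, 0.5, 0.5)),
    ))
    sub = build_submission(gender="male", ethnicity="white")
    v = make_class_vector(sub, scheme)
    assert v.values[scheme.index_of("ethnicity", "white")] == 0.5
    assert v.values[scheme.index_of("gender", "male")] == 1.0


def test_unknown_level_names_field_and_value(scheme):
    sub = build_submission()
    sub.levels["diabetes"] = "maybe"
    with pytest.raises(ValidationError, match="diabetes.*maybe"):
        make_class_vector(sub, scheme)


# ------------------------------------------------------------- aggregation

def test_empty_history_gives_zero_aggregates(scheme):
    control, experimental = aggregate_history([], scheme)
    assert control.count == 0 and experimental.count == 0
    assert not control.totals.any() and not experimental.totals.any()


def test_three_record_aggregation_matches_elementwise_oracle(scheme):
    records = [
        build_record(scheme, {"gender": "male", "age_class": "young",
                              "diabetes": "no", "ethnicity": "white"}, "option1"),
        build_record(scheme, {"gender": "female", "age_class": "old",
                              "diabetes": "yes", "ethnicity": "black"}, "option1"),
        build_record(scheme, {"gender": "male", "age_class": "old",
                              "diabetes": "no", "ethnicity": "asian"}, "option2"),
    ]
    control, experimental = aggregate_history(records, scheme)
    # independent oracle: naive per-element summation
    expect_c = np.zeros(scheme.n_classes)
    expect_e = np.zeros(scheme.n_classes)
    for rec in records:
        target = expect_c if rec.vector.values[-2] else expect_e
        for i in range(scheme.n_classes):
            target[i] += rec.vector.values[i]
    assert np.array_equal(control.totals, expect_c)
    assert np.array_equal(experimental.totals, expect_e)
    assert (control.count, experimental.count) == (2, 1)


def test_per_factor_totals_conserve_arm_count(scheme):
    rng = np.random.default_rng(5)
    levels_of = {f.name: f.levels for f in scheme.factors}
    records = [
        build_record(
            scheme,
            {name: lv[rng.integers(len(lv))] for name, lv in levels_of.items()},
            "option1" if rng.random() < 0.5 else "option2",
            participant_id=f"R{i}",
        )
        for i in range(40)
    ]
    control, experimental = aggregate_history(records, scheme)
    for agg in (control, experimental):
        for factor in scheme.factors:
            pos = scheme.positions_of(factor.name)
            assert agg.totals[pos.start:pos.stop].sum() == agg.count


def test_record_with_two_outcome_flags_is_corrupt(scheme):
    bad = build_record(scheme, {"gender": "male", "age_class": "young",
                                "diabetes": "no", "ethnicity": "white"})
    bad.vector.values[-1] = 1.0  # both flags now set
    with pytest.raises(CorruptHistoryError, match="2 outcome flags"):
        aggregate_history([bad], scheme)


# ------------------------------------------------------------------ scores

def _matched_aggregates(scheme, control_vals, experimental_vals):
    """Aggregates whose totals at a male/young/no/white participant's matched
    classes are the given values; other positions filled arbitrarily."""
    c = np.arange(scheme.n_classes, dtype=float)
    e = np.arange(scheme.n_classes, dtype=float)[::-1].copy()
    matched = [scheme.index_of("gender", "male"), scheme.index_of("age_class", "young"),
               scheme.index_of("diabetes", "no"), scheme.index_of("ethnicity", "white")]
    c[matched] = control_vals
    e[matched] = experimental_vals
    return ArmAggregate(c, 0), ArmAggregate(e, 0)


def test_worked_example_scores_95_and_98(scheme):
    control, experimental = _matched_aggregates(scheme, [25, 26, 14, 30], [23, 22, 18, 35])
    v = make_class_vector(build_submission(gender="male", age_years=40,
                                           diabetes="no", ethnicity="white"), scheme)
    assert arm_scores(v, control, experimental) == (95.0, 98.0)


def test_empty_trial_scores_zero(scheme, submission):
    v = make_class_vector(submission, scheme)
    control, experimental = aggregate_history([], scheme)
    assert arm_scores(v, control, experimental) == (0.0, 0.0)


def test_scores_match_brute_force_loop_oracle(scheme):
    rng = np.random.default_rng(17)
    levels_of = {f.name: f.levels for f in scheme.factors}
    for _ in range(1000):
        sub = build_submission(
            gender=levels_of["gender"][rng.integers(2)],
            age_years=int(rng.integers(18, 91)),
            diabetes=levels_of["diabetes"][rng.integers(2)],
            ethnicity=levels_of["ethnicity"][rng.integers(4)],
        )
        v = make_class_vector(sub, scheme)
        control = ArmAggregate(rng.integers(0, 50, scheme.n_classes).astype(float), 0)
        experimental = ArmAggregate(rng.integers(0, 50, scheme.n_classes).astype(float), 0)
        cs, es = arm_scores(v, control, experimental)
        oracle_c = oracle_e = 0.0
        for i in range(scheme.n_classes):
            if v.values[i] != 0:
                oracle_c += control.totals[i]
                oracle_e += experimental.totals[i]
        assert cs == oracle_c and es == oracle_e


def test_length_mismatch_is_scheme_error(scheme, submission):
    v = make_class_vector(submission, scheme)
    short = ArmAggregate(np.zeros(scheme.n_classes - 1), 0)
    ok = ArmAggregate(np.zeros(scheme.n_classes), 0)
    with pytest.raises(SchemeMismatchError):
        arm_scores(v, short, ok)


# ------------------------------------------------------------ biased coin

def test_probability_one_always_selects_option1():
    rng = np.random.default_rng(0)
    assert all(randomise_arm(1.0, rng)[0] == OPTION1 for _ in range(1000))


def test_probability_zero_never_selects_option1():
    rng = np.random.default_rng(0)
    assert all(randomise_arm(0.0, rng)[0] == OPTION2 for _ in range(1000))


def test_fair_coin_frequency_within_three_sigma():
    rng = np.random.default_rng(123)
    n = 100_000
    hits = sum(randomise_arm(0.5, rng)[0] == OPTION1 for _ in range(n))
    assert abs(hits / n - 0.5) < 0.005  # 3 sigma ~ 0.0047


def test_out_of_range_probability_rejected():
    rng = np.random.default_rng(0)
    for p in (-0.1, 1.1):
        with pytest.raises(ValidationError):
            randomise_arm(p, rng)


# -------------------------------------------------------------- decisions

def test_worked_example_allocates_to_control_deterministically(scheme):
    control, experimental = _matched_aggregates(scheme, [25, 26, 14, 30], [23, 22, 18, 35])
    v = make_class_vector(build_submission(gender="male", age_years=40,
                                           diabetes="no", ethnicity="white"), scheme)
    d = decide_allocation(v, control, experimental, 1.0, np.random.default_rng(0))
    assert d.arm == OPTION1
    assert d.mode == MODE_DETERMINISTIC
    assert d.coin_draw is None
    assert (d.control_score, d.experimental_score) == (95.0, 98.0)


def test_first_participant_is_always_randomized(scheme, submission):
    v = make_class_vector(submission, scheme)
    control, experimental = aggregate_history([], scheme)
    d = decide_allocation(v, control, experimental, 1.0, np.random.default_rng(9))
    assert d.mode == MODE_TIE_RANDOM
    assert d.coin_draw is not None


def test_tie_break_is_fair_regardless_of_r(scheme, submission):
    # equal scores use probability 0.5 even under deterministic minimization
    v = make_class_vector(submission, scheme)
    empty_c, empty_e = aggregate_history([], scheme)
    rng = np.random.default_rng(2024)
    n = 20_000
    control_hits = sum(
        decide_allocation(v, empty_c, empty_e, 1.0, rng).arm == OPTION1
        for _ in range(n)
    )
    assert abs(control_hits / n - 0.5) < 0.011  # 3 sigma over 20,000


def test_biased_coin_goes_against_preference_at_one_minus_r(scheme):
    control, experimental = _matched_aggregates(scheme, [10, 10, 10, 10], [20, 20, 20, 20])
    v = make_class_vector(build_submission(gender="male", age_years=40,
                                           diabetes="no", ethnicity="white"), scheme)
    rng = np.random.default_rng(7)
    n = 100_000
    against = sum(
        decide_allocation(v, control, experimental, 0.8, rng).arm == OPTION2
        for _ in range(n)
    )
    assert abs(against / n - 0.20) < 0.004  # 3 sigma ~ 0.0038


def test_deterministic_branch_consumes_no_rng(scheme):
    control, experimental = _matched_aggregates(scheme, [1, 1, 1, 1], [5, 5, 5, 5])
    v = make_class_vector(build_submission(gender="male", age_years=40,
                                           diabetes="no", ethnicity="white"), scheme)
    rng = np.random.default_rng(31)
    decide_allocation(v, control, experimental, 1.0, rng)
    # stream untouched: next draw equals the first draw of a fresh generator
    assert rng.random() == np.random.default_rng(31).random()


def test_r_below_half_is_rejected_with_explanation(scheme, submission):
    v = make_class_vector(submission, scheme)
    c, e = aggregate_history([], scheme)
    with pytest.raises(ConfigurationError, match="pure randomization"):
        decide_allocation(v, c, e, 0.3, np.random.default_rng(0))


# ------------------------------------------------------------ finalization

@pytest.mark.parametrize("arm,expect", [(OPTION1, (1.0, 0.0)), (OPTION2, (0.0, 1.0))])
def test_finalize_sets_exactly_one_outcome_flag(scheme, submission, arm, expect):
    v = make_class_vector(submission, scheme)
    d = decide_allocation(v, *aggregate_history([], scheme), 1.0, np.random.default_rng(0))
    d = type(d)(arm, d.control_score, d.experimental_score, d.mode, d.coin_draw)
    rec = finalize_record(submission, v, d, scheme)
    assert tuple(rec.vector.values[-2:]) == expect
    assert rec.arm == arm
    assert rec.participant_id == submission.participant_id
    assert rec.weekday == "Wednesday"  # 2014-10-29


def test_finalize_then_aggregate_single_record_identity(scheme, submission):
    v = make_class_vector(submission, scheme)
    d = decide_allocation(v, *aggregate_history([], scheme), 1.0, np.random.default_rng(1))
    rec = finalize_record(submission, v, d, scheme)
    control, experimental = aggregate_history([rec], scheme)
    winner = control if d.arm == OPTION1 else experimental
    assert np.array_equal(winner.totals, v.values[: scheme.n_classes])
    assert winner.count == 1


def test_double_finalization_is_rejected(scheme, submission):
    v = make_class_vector(submission, scheme)
    d = decide_allocation(v, *aggregate_history([], scheme), 1.0, np.random.default_rng(1))
    rec = finalize_record(submission, v, d, scheme)
    with pytest.raises(DoubleAllocationError):
        finalize_record(submission, rec.vector, d, scheme)
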
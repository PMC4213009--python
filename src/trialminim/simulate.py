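"""Trial simulation: synthetic participant streams and balance metrics.

The simulator is the package's evaluation surface: it generates synthetic
participant streams from per-factor prevalences, replays them through the
allocation algorithm, and measures how evenly each factor level ends up
distributed between the arms. Comparing the randomization element r = 1
(deterministic minimization) against r = 0.5 (pure randomization) on the
same streams quantifies what minimization buys.

Factor levels are drawn independently of each other — the generator models
marginal prevalences only, not the correlation structure of a real clinic
population.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core
from .errors import ValidationError
from .intake import EthnicityVocabulary, ParticipantSubmission, default_vocabulary
from .scheme import OPTION1, FactorScheme, default_scheme
from .state import DEFAULT_DELIMITER, write_state_file

_BASE_TIME = _dt.datetime(2014, 10, 29, 9, 0, 0)


@dataclass(frozen=True)
class PopulationModel:
    """Per-factor level prevalences for a synthetic participant stream."""

    prevalences: dict[str, dict[str, float]]
    n: int
    seed: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"n: need at least 1 participant, got {self.n}")
        for factor, probs in self.prevalences.items():
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"{factor}: prevalences must sum to 1, got {total!r}"
                )
            if any(p < 0 for p in probs.values()):
                raise ValidationError(f"{factor}: prevalences must be non-negative")


def default_population_model(n: int = 152, seed: int | None = None) -> PopulationModel:
    """Default synthetic population: a small UK kidney-clinic-like cohort.

    Marginals: half male, just under half below the age threshold, about a
    quarter diabetic, predominantly white — the kind of cohort a small
    single-country chronic-kidney-disease trial recruits.
    """
    return PopulationModel(
        prevalences={
            "gender": {"male": 76 / 152, "female": 76 / 152},
            "age_class": {"young": 71 / 152, "old": 81 / 152},
            "diabetes": {"no": 113 / 152, "yes": 39 / 152},
            "ethnicity": {
                "white": 142 / 152,
                "black": 5 / 152,
                "asian": 4 / 152,
                "chinese": 1 / 152,
            },
        },
        n=n,
        seed=seed,
    )


def generate_stream(
    model: PopulationModel,
    scheme: FactorScheme | None = None,
    vocabulary: EthnicityVocabulary | None = None,
    age_threshold: int = 65,
) -> list[ParticipantSubmission]:
    """Draw a reproducible synthetic submission stream from the model.

    Each factor level is sampled independently per participant. Documentary
    fields (age in years, detailed ethnicity code, timestamps) are filled in
    consistently with the drawn levels so the stream round-trips through the
    full intake/reporting stack.
    """
    scheme = scheme or default_scheme()
    vocabulary = vocabulary or default_vocabulary()
    rng = np.random.default_rng(model.seed)
    missing = [f.name for f in scheme.factors if f.name not in model.prevalences]
    if missing:
        raise ValidationError(f"model lacks prevalences for factors: {missing}")

    stream = []
    for i in range(model.n):
        levels = {}
        for factor in scheme.factors:
            probs = model.prevalences[factor.name]
            unknown = set(probs) - set(factor.levels)
            if unknown:
                raise ValidationError(
                    f"{factor.name}: prevalence levels {sorted(unknown)} not in scheme"
                )
            names = list(probs)
            levels[factor.name] = names[
                int(rng.choice(len(names), p=np.array(list(probs.values()))))
            ]
        age_class = levels.get("age_class", "young")
        if age_class == "old":
            age = int(rng.integers(age_threshold, 91))
        else:
            age = int(rng.integers(18, age_threshold))
        category = levels.get("ethnicity", vocabulary.categories[0])
        codes = vocabulary.codes_for(category)
        code = codes[int(rng.integers(len(codes)))]
        timestamp = _BASE_TIME + _dt.timedelta(minutes=i)
        stream.append(
            ParticipantSubmission(
                participant_id=f"SIM{i:05d}",
                submitter_email="simulator@local",
                gender=levels.get("gender", ""),
                age_years=age,
                diabetes=levels.get("diabetes", ""),
                ethnicity_code=code,
                ethnicity=category,
                age_class=age_class,
                timestamp=timestamp,
                levels=levels,
            )
        )
    return stream


@dataclass
class TrialResult:
    """Replay of one simulated trial."""

    records: list[core.AllocationRecord]
    decisions: list[core.AllocationDecision]
    control: core.ArmAggregate
    experimental: core.ArmAggregate
    scheme: FactorScheme = field(default_factory=default_scheme)


def run_trial(
    stream,
    scheme: FactorScheme | None = None,
    r: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    state_path: str | Path | None = None,
    delimiter: str = DEFAULT_DELIMITER,
) -> TrialResult:
    """Replay a submission stream through the allocation algorithm.

    Maintains the arm aggregates incrementally, which is equivalent to the
    full load-decide-append transaction on a fresh state file (the engine
    re-derives exactly these aggregates from the file each time). If
    ``state_path`` is given, the resulting state file is written and is
    loadable by the state store.
    """
    scheme = scheme or default_scheme()
    rng = rng if rng is not None else np.random.default_rng(seed)
    control = core.ArmAggregate.empty(scheme)
    experimental = core.ArmAggregate.empty(scheme)
    records, decisions = [], []
    for submission in stream:
        vector = core.make_class_vector(submission, scheme)
        decision = core.decide_allocation(vector, control, experimental, r, rng)
        record = core.finalize_record(submission, vector, decision, scheme)
        (control if decision.arm == OPTION1 else experimental).add(record.vector)
        records.append(record)
        decisions.append(decision)
    if state_path is not None:
        write_state_file(records, state_path, scheme, delimiter)
    return TrialResult(records, decisions, control, experimental, scheme)


@dataclass(frozen=True)
class BalanceReport:
    """Per-class arm balance of one trial, shaped as a two-column count table."""

    table: pd.DataFrame  # columns: factor, level, control, experimental, imbalance
    arm_sizes: tuple[int, int]

    @property
    def max_imbalance(self) -> float:
        """Largest per-class |control total - experimental total|."""
        return float(self.table["imbalance"].max()) if len(self.table) else 0.0

    @property
    def arm_size_difference(self) -> int:
        return abs(self.arm_sizes[0] - self.arm_sizes[1])


def balance_report(result: TrialResult) -> BalanceReport:
    """Tabulate per-class control/experimental totals and their imbalance."""
    scheme = result.scheme
    rows = []
    for pos, (factor, level) in enumerate(scheme.class_labels):
        c = float(result.control.totals[pos])
        e = float(result.experimental.totals[pos])
        rows.append(
            {
                "factor": factor,
                "level": level,
                "control": c,
                "experimental": e,
                "imbalance": abs(c - e),
            }
        )
    table = pd.DataFrame(rows, columns=["factor", "level", "control", "experimental", "imbalance"])
    return BalanceReport(table, (result.control.count, result.experimental.count))


def compare_strategies(
    model: PopulationModel,
    r_values=(1.0, 0.8, 0.5),
    replicates: int = 200,
    seed: int = 0,
    scheme: FactorScheme | None = None,
) -> pd.DataFrame:
    """Monte Carlo comparison of allocation strategies on shared streams.

    Each replicate draws one synthetic stream and replays it once per value
    of the randomization element (paired design: every r sees the same
    streams). Returns one row per r with the mean and central 95% range of
    the maximum per-class imbalance and of the arm-size difference.
    """
    if replicates < 2:
        raise ValidationError(f"replicates: need at least 2, got {replicates}")
    scheme = scheme or default_scheme()
    ss = np.random.SeedSequence(seed)
    stream_seeds = ss.spawn(replicates)
    rows = []
    for r in r_values:
        max_imb = np.empty(replicates)
        size_diff = np.empty(replicates)
        for rep in range(replicates):
            child = stream_seeds[rep]
            stream_seed, coin_seed = child.generate_state(2)
            rep_model = PopulationModel(
                model.prevalences, model.n, seed=int(stream_seed % (2**31))
            )
            stream = generate_stream(rep_model, scheme)
            rng = np.random.default_rng(int(coin_seed % (2**31)) + hash(r) % 1000)
            result = run_trial(stream, scheme, r=r, rng=rng)
            report = balance_report(result)
            max_imb[rep] = report.max_imbalance
            size_diff[rep] = report.arm_size_difference
        rows.append(
            {
                "r": r,
                "mean_max_imbalance": max_imb.mean(),
                "max_imbalance_q025": float(np.quantile(max_imb, 0.025)),
                "max_imbalance_q975": float(np.quantile(max_imb, 0.975)),
                "mean_arm_size_diff": size_diff.mean(),
                "arm_size_diff_q025": float(np.quantile(size_diff, 0.025)),
                "arm_size_diff_q975": float(np.quantile(size_diff, 0.975)),
            }
        )
    return pd.DataFrame(rows)
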
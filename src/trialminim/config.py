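"""Trial configuration: one YAML file fixing every tunable of a trial.

The configuration owns the factor scheme (names, levels, per-level
weights), the arm display labels, the randomization element r, the age
threshold, the detailed-ethnicity vocabulary, the state/archive/outbox
paths, the notification recipients and the RNG seed policy. It is loaded
once per transaction and validated eagerly, so a misconfigured trial fails
before any participant is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .intake import DEFAULT_AGE_THRESHOLD, EthnicityVocabulary, default_vocabulary
from .scheme import DEFAULT_ARM_LABELS, Factor, FactorScheme, default_scheme
from .state import DEFAULT_DELIMITER


@dataclass(frozen=True)
class Recipients:
    nurse: str = "nurse@example.org"
    admin: str = "admin@example.org"
    extra: tuple[str, ...] = ()


def _level_name(value) -> str:
    # YAML 1.1 parses bare no/yes as booleans; map them back to level names.
    if value is True:
        return "yes"
    if value is False:
        return "no"
    return str(value)


@dataclass
class EngineConfig:
    """Everything a trial needs, resolved and validated."""

    scheme: FactorScheme = field(default_factory=default_scheme)
    vocabulary: EthnicityVocabulary = field(default_factory=default_vocabulary)
    randomisation_element: float = 1.0
    age_threshold: int = DEFAULT_AGE_THRESHOLD
    delimiter: str = DEFAULT_DELIMITER
    recipients: Recipients = field(default_factory=Recipients)
    seed: int | None = None
    state_path: Path = Path("state.txt")
    archive_path: Path = Path("archive.txt")
    outbox_path: Path = Path("outbox")
    trial_name: str = "study"

    def __post_init__(self):
        self.state_path = Path(self.state_path)
        self.archive_path = Path(self.archive_path)
        self.outbox_path = Path(self.outbox_path)
        self.validate()

    def validate(self) -> None:
        r = self.randomisation_element
        if not 0.5 <= r <= 1.0:
            raise ConfigurationError(
                f"randomisation_element must be in [0.5, 1], got {r}: it is the "
                "probability of following the minimization-preferred arm "
                "(1 = deterministic minimization, 0.5 = pure randomization)"
            )
        if not self.delimiter or "\n" in self.delimiter:
            raise ConfigurationError("delimiter must be non-empty and newline-free")
        if not 0 < self.age_threshold <= 150:
            raise ConfigurationError(
                f"age_threshold must be in (0, 150], got {self.age_threshold}"
            )
        eth = next((f for f in self.scheme.factors if f.name == "ethnicity"), None)
        if eth is not None and set(self.vocabulary.categories) != set(eth.levels):
            raise ConfigurationError(
                "ethnicity vocabulary categories "
                f"{sorted(self.vocabulary.categories)} do not match the scheme's "
                f"ethnicity levels {sorted(eth.levels)}"
            )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "trial_name": self.trial_name,
            "randomisation_element": self.randomisation_element,
            "age_threshold": self.age_threshold,
            "delimiter": self.delimiter,
            "seed": self.seed,
            "arms": {
                "control": self.scheme.arm_labels[0],
                "experimental": self.scheme.arm_labels[1],
            },
            "factors": [
                {
                    "name": f.name,
                    "levels": list(f.levels),
                    "weights": {lvl: w for lvl, w in zip(f.levels, f.weights)},
                }
                for f in self.scheme.factors
            ],
            "ethnicity_codes": dict(self.vocabulary.codes),
            "recipients": {
                "nurse": self.recipients.nurse,
                "admin": self.recipients.admin,
                "extra": list(self.recipients.extra),
            },
            "paths": {
                "state": str(self.state_path),
                "archive": str(self.archive_path),
                "outbox": str(self.outbox_path),
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "EngineConfig":
        arms = data.get("arms", {})
        arm_labels = (
            str(arms.get("control", DEFAULT_ARM_LABELS[0])),
            str(arms.get("experimental", DEFAULT_ARM_LABELS[1])),
        )
        if "factors" in data:
            factors = []
            for spec in data["factors"]:
                levels = tuple(_level_name(l) for l in spec["levels"])
                weights_map = {
                    _level_name(k): float(v)
                    for k, v in (spec.get("weights") or {}).items()
                }
                weights = tuple(weights_map.get(lvl, 1.0) for lvl in levels)
                factors.append(Factor(str(spec["name"]), levels, weights))
            scheme = FactorScheme(tuple(factors), arm_labels)
        else:
            scheme = default_scheme(arm_labels)
        if "ethnicity_codes" in data:
            vocabulary = EthnicityVocabulary(
                {str(k): _level_name(v) for k, v in data["ethnicity_codes"].items()}
            )
        else:
            vocabulary = default_vocabulary()
        recipients_data = data.get("recipients", {})
        recipients = Recipients(
            nurse=str(recipients_data.get("nurse", Recipients.nurse)),
            admin=str(recipients_data.get("admin", Recipients.admin)),
            extra=tuple(recipients_data.get("extra") or ()),
        )
        paths = data.get("paths", {})
        seed = data.get("seed")
        return cls(
            scheme=scheme,
            vocabulary=vocabulary,
            randomisation_element=float(data.get("randomisation_element", 1.0)),
            age_threshold=int(data.get("age_threshold", DEFAULT_AGE_THRESHOLD)),
            delimiter=str(data.get("delimiter", DEFAULT_DELIMITER)),
            recipients=recipients,
            seed=None if seed is None else int(seed),
            state_path=Path(paths.get("state", "state.txt")),
            archive_path=Path(paths.get("archive", "archive.txt")),
            outbox_path=Path(paths.get("outbox", "outbox")),
            trial_name=str(data.get("trial_name", "study")),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False, default_flow_style=False),
            encoding="utf-8",
        )


def load_config(path: str | Path) -> EngineConfig:
    """Load and validate a trial configuration from YAML.

    Paths inside the file are resolved relative to the file's directory, so
    a trial directory is relocatable as a unit.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    except FileNotFoundError:
        raise ConfigurationError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"config file {path} is not valid YAML: {exc}") from None
    cfg = EngineConfig.from_dict(data)
    base = path.parent
    for attr in ("state_path", "archive_path", "outbox_path"):
        p = getattr(cfg, attr)
        if not p.is_absolute():
            setattr(cfg, attr, base / p)
    return cfg
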
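"""Factor schemes: the ordered layout of allocation classes.

A trial's *factor scheme* fixes, once and for all, the layout of every class
vector, arm aggregate and state-file line: factors in declared order, levels
in declared order, and the two outcome classes (option 1 = control,
option 2 = experimental) always occupying the last two positions.

Each level carries a weight (default 1.0) which is the numeric value a
participant contributes at that level; lowering a factor's weights makes it
count proportionally less in the minimization score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

#: Canonical arm identifiers used throughout the package.
OPTION1 = "option1"  # control
OPTION2 = "option2"  # experimental

DEFAULT_ARM_LABELS = ("Control Arm", "Experimental Arm")


@dataclass(frozen=True)
class Factor:
    """One allocation factor: an ordered set of mutually exclusive levels."""

    name: str
    levels: tuple[str, ...]
    weights: tuple[float, ...] = ()

    def __post_init__(self):
        levels = tuple(str(l) for l in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise ConfigurationError(
                f"factor {self.name!r} needs at least 2 levels, got {len(levels)}"
            )
        if len(set(levels)) != len(levels):
            raise ConfigurationError(f"factor {self.name!r} has duplicate level names")
        weights = self.weights or tuple(1.0 for _ in levels)
        weights = tuple(float(w) for w in weights)
        if len(weights) != len(levels):
            raise ConfigurationError(
                f"factor {self.name!r}: {len(weights)} weights for {len(levels)} levels"
            )
        if any(w < 0 for w in weights):
            raise ConfigurationError(f"factor {self.name!r}: weights must be non-negative")
        object.__setattr__(self, "weights", weights)

    def weight_of(self, level: str) -> float:
        return self.weights[self.levels.index(level)]


@dataclass(frozen=True)
class FactorScheme:
    """Ordered collection of factors plus the two arm display labels.

    The scheme induces a total, stable class ordering: the concatenation of
    each factor's levels in declared order, followed by the two outcome
    classes. ``n_classes`` counts allocation classes only (outcomes excluded).
    """

    factors: tuple[Factor, ...]
    arm_labels: tuple[str, str] = DEFAULT_ARM_LABELS
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        factors = tuple(self.factors)
        object.__setattr__(self, "factors", factors)
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ConfigurationError("factor names must be unique")
        if len(self.arm_labels) != 2:
            raise ConfigurationError("exactly two arm labels are required")
        index, pos = {}, 0
        for f in factors:
            for lvl in f.levels:
                index[(f.name, lvl)] = pos
                pos += 1
        object.__setattr__(self, "_index", index)

    @property
    def n_classes(self) -> int:
        """Number of allocation classes (sum of level counts)."""
        return sum(len(f.levels) for f in self.factors)

    @property
    def vector_length(self) -> int:
        """Allocation classes plus the two outcome positions."""
        return self.n_classes + 2

    @property
    def option1_pos(self) -> int:
        return self.n_classes

    @property
    def option2_pos(self) -> int:
        return self.n_classes + 1

    @property
    def class_labels(self) -> list[tuple[str, str]]:
        """(factor name, level name) for every allocation class, in order."""
        return [(f.name, lvl) for f in self.factors for lvl in f.levels]

    def index_of(self, factor: str, level: str) -> int:
        return self._index[(factor, level)]

    def positions_of(self, factor_name: str) -> range:
        start = 0
        for f in self.factors:
            if f.name == factor_name:
                return range(start, start + len(f.levels))
            start += len(f.levels)
        raise KeyError(factor_name)

    def arm_label(self, arm: str) -> str:
        """Display string for ``option1``/``option2``."""
        if arm == OPTION1:
            return self.arm_labels[0]
        if arm == OPTION2:
            return self.arm_labels[1]
        raise ValueError(f"unknown arm {arm!r}")


def default_scheme(arm_labels: tuple[str, str] = DEFAULT_ARM_LABELS) -> FactorScheme:
    """The shipped four-factor scheme: 10 allocation classes.

    Gender (2), age class (2), diabetes (2) and aggregated ethnicity (4).
    """
    return FactorScheme(
        factors=(
            Factor("gender", ("male", "female")),
            Factor("age_class", ("young", "old")),
            Factor("diabetes", ("no", "yes")),
            Factor("ethnicity", ("white", "black", "asian", "chinese")),
        ),
        arm_labels=tuple(arm_labels),
    )
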
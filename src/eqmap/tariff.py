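"""EQ-5D-3L descriptive system and preference-based (tariff) scoring.

The EQ-5D-3L describes health on five dimensions (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), each at one of
three levels: no problems (1), some problems (2), extreme problems (3).
This yields 3**5 = 243 distinct health states, written as five-digit
profiles such as ``"21232"`` in questionnaire order.

A tariff (value set) maps each profile to a utility anchored at 1 for
full health (``11111``) and 0 for dead, with negative values allowed for
states valued worse than dead. The bundled default is the UK
time-trade-off value set, an additive decrement model: starting from 1,
subtract a constant if any dimension is above level 1, a per-dimension
decrement for each level-2 or level-3 response, and an extra "N3"
decrement once if any dimension is at level 3. Under that set the index
spans [-0.594, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

#: The five dimensions in questionnaire order.
DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

LEVELS = (1, 2, 3)

#: Size of the EQ-5D-3L state space.
N_STATES = 3 ** len(DIMENSIONS)


class TariffError(ValueError):
    """Raised for invalid or incomplete tariff coefficient tables."""


@dataclass(frozen=True)
class HealthState:
    """One EQ-5D-3L profile: a level in {1, 2, 3} for each dimension."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in LEVELS:
                raise ValueError(
                    f"invalid level {level!r} for dimension {dim!r}; "
                    "levels must be 1, 2 or 3"
                )

    @classmethod
    def from_string(cls, profile: str) -> "HealthState":
        """Parse a five-character profile such as ``"21232"``."""
        if len(profile) != 5 or not profile.isdigit():
            raise ValueError(
                f"profile must be five digits in questionnaire order, got {profile!r}"
            )
        return cls(*(int(ch) for ch in profile))

    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, dim) for dim in DIMENSIONS)

    def __str__(self) -> str:
        return "".join(str(level) for level in self.levels())


@dataclass(frozen=True)
class TariffCoefficients:
    """Additive decrement table defining a preference-based index.

    ``score = full_health_value
              - constant_any_problem * [any level > 1]
              - sum of per-dimension level-2/level-3 decrements
              - any_level3_decrement * [any level == 3]``
    """

    full_health_value: float
    constant_any_problem: float
    level2_decrement: Mapping[str, float]
    level3_decrement: Mapping[str, float]
    any_level3_decrement: float
    name: str = "custom"

    def __post_init__(self) -> None:
        for table, label in (
            (self.level2_decrement, "level-2"),
            (self.level3_decrement, "level-3"),
        ):
            missing = [d for d in DIMENSIONS if d not in table]
            if missing:
                raise TariffError(
                    f"missing {label} decrement for dimension(s): {', '.join(missing)}"
                )
        values = {
            "constant": self.constant_any_problem,
            "n3": self.any_level3_decrement,
        }
        for dim in DIMENSIONS:
            values[f"{dim}_2"] = self.level2_decrement[dim]
            values[f"{dim}_3"] = self.level3_decrement[dim]
        negative = {k: v for k, v in values.items() if v < 0}
        if negative:
            raise TariffError(f"decrements must be non-negative; got {negative}")

    def worst_state_value(self) -> float:
        """Utility of profile 33333 under this tariff."""
        return score_state(HealthState(3, 3, 3, 3, 3), self)


def score_state(state: HealthState | str, tariff: TariffCoefficients) -> float:
    """Utility of one health state under ``tariff``.

    ``state`` may be a :class:`HealthState` or a five-digit profile string.
    """
    if isinstance(state, str):
        state = HealthState.from_string(state)
    levels = state.levels()
    utility = tariff.full_health_value
    if any(level > 1 for level in levels):
        utility -= tariff.constant_any_problem
    for dim, level in zip(DIMENSIONS, levels):
        if level == 2:
            utility -= tariff.level2_decrement[dim]
        elif level == 3:
            utility -= tariff.level3_decrement[dim]
    if any(level == 3 for level in levels):
        utility -= tariff.any_level3_decrement
    return utility


def score_profiles(levels: np.ndarray, tariff: TariffCoefficients) -> np.ndarray:
    """Vectorised scoring of an ``(n, 5)`` integer array of levels.

    Columns follow questionnaire order. Invalid levels raise with the
    offending dimension named.
    """
    levels = np.asarray(levels)
    if levels.ndim != 2 or levels.shape[1] != len(DIMENSIONS):
        raise ValueError(f"expected an (n, 5) array of levels, got shape {levels.shape}")
    for j, dim in enumerate(DIMENSIONS):
        bad = ~np.isin(levels[:, j], LEVELS)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"invalid level {levels[row, j]!r} for dimension {dim!r} at row {row}"
            )
    utility = np.full(levels.shape[0], float(tariff.full_health_value))
    utility -= tariff.constant_any_problem * (levels > 1).any(axis=1)
    for j, dim in enumerate(DIMENSIONS):
        utility -= tariff.level2_decrement[dim] * (levels[:, j] == 2)
        utility -= tariff.level3_decrement[dim] * (levels[:, j] == 3)
    utility -= tariff.any_level3_decrement * (levels == 3).any(axis=1)
    return utility


def enumerate_states() -> list[HealthState]:
    """All 243 health states in lexicographic (questionnaire) order."""
    return [
        HealthState(*levels)
        for levels in itertools.product(LEVELS, repeat=len(DIMENSIONS))
    ]


_REQUIRED_KEYS = ("constant", "n3") + tuple(
    f"{dim}_{level}" for dim in DIMENSIONS for level in (2, 3)
)

#: Printed endpoint anchors the bundled UK value set must reproduce.
_UK_ANCHORS = (("11111", 1.0), ("33333", -0.594))


def _from_flat(raw: Mapping[str, float], name: str = "custom") -> TariffCoefficients:
    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise TariffError(f"tariff table is missing coefficient(s): {', '.join(missing)}")
    return TariffCoefficients(
        full_health_value=float(raw.get("full_health", 1.0)),
        constant_any_problem=float(raw["constant"]),
        level2_decrement={d: float(raw[f"{d}_2"]) for d in DIMENSIONS},
        level3_decrement={d: float(raw[f"{d}_3"]) for d in DIMENSIONS},
        any_level3_decrement=float(raw["n3"]),
        name=name,
    )


def load_tariff(source: Mapping[str, float] | str | Path | None = None) -> TariffCoefficients:
    """Load a tariff coefficient table.

    With no argument, returns the bundled UK TTO value set, validated
    against its two published endpoint anchors (1 at 11111, -0.594 at
    33333); failure of that check is a hard error. ``source`` may also
    be a flat mapping or a path to a YAML file with keys ``constant``,
    ``n3`` and ``{dimension}_{level}`` for levels 2 and 3.
    """
    if source is None:
        with resources.files("eqmap.data").joinpath("uk_tto.yaml").open("r") as fh:
            raw = yaml.safe_load(fh)
        tariff = _from_flat(raw, name="uk_tto")
        for profile, anchor in _UK_ANCHORS:
            got = score_state(profile, tariff)
            if abs(got - anchor) > 1e-9:
                raise TariffError(
                    f"bundled UK tariff fails its endpoint anchor: "
                    f"score({profile}) = {got!r}, expected {anchor}"
                )
        return tariff
    if isinstance(source, (str, Path)):
        with open(source, "r") as fh:
            raw = yaml.safe_load(fh)
        return _from_flat(raw, name=Path(source).stem)
    return _from_flat(source)
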